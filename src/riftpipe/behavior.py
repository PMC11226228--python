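"""Behavioral reading measures and the brain-behavior correlation.

Reading speed is words per second in congruent sentences; per sentence the
reading time is the sum of all fixation durations in the trial (the
simulation does not model the on-screen gaze-trigger timing, so fixation time
is the deterministic equivalent).  The brain-behavior link is the Spearman
rank correlation between each subject's pre-target coherence congruency
difference (incongruent - congruent) and their reading speed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .events import first_fixation_durations, total_gaze_and_refixation

__all__ = [
    "reading_speed",
    "speed_coherence_correlation",
    "behavioral_summary",
    "paired_ffd_test",
]


def reading_speed(
    events: pd.DataFrame,
    words_per_sentence: int,
    condition: str = "congruent",
) -> pd.Series:
    """Words read per second, per subject, from one condition's sentences.

    speed = (words per sentence * number of sentences) / (total reading time),
    with reading time per sentence the summed fixation durations of the trial.
    """
    df = events[events["condition"] == condition]
    if df.empty:
        raise ValueError(f"no events in condition {condition!r}")
    per_trial = df.groupby(["subject_id", "trial_id"])["duration_ms"].sum()
    if (per_trial <= 0).any():
        raise ValueError("trial with zero reading time")
    per_subject = per_trial.groupby("subject_id").agg(["sum", "count"])
    speed = words_per_sentence * per_subject["count"] / (per_subject["sum"] / 1000.0)
    speed.name = "words_per_second"
    return speed


def speed_coherence_correlation(
    coh_diff_per_subject, speed_per_subject
) -> tuple[float, float]:
    """Spearman correlation of the coherence congruency effect with speed.

    Inputs are paired per-subject values (n >= 5).  Ties get midranks.
    Returns (rho, two-sided p).
    """
    x = np.asarray(coh_diff_per_subject, dtype=float)
    y = np.asarray(speed_per_subject, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need paired per-subject values with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def paired_ffd_test(events: pd.DataFrame, word_offset: int) -> dict:
    """Paired t-test of per-subject mean first-fixation durations by condition."""
    ffd = first_fixation_durations(events, word_offset)
    means = ffd.pivot_table(
        index="subject_id", columns="condition", values="duration_ms", aggfunc="mean"
    ).dropna()
    t, p = scipy.stats.ttest_rel(means["incongruent"], means["congruent"])
    diff = (means["incongruent"] - means["congruent"]).to_numpy()
    d = float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else np.nan
    return {
        "word_offset": word_offset,
        "mean_incongruent_ms": float(means["incongruent"].mean()),
        "mean_congruent_ms": float(means["congruent"].mean()),
        "t": float(t),
        "p": float(p),
        "cohens_d": d,
        "n_subjects": int(len(means)),
    }


def behavioral_summary(
    events: pd.DataFrame, words_per_sentence: int
) -> pd.DataFrame:
    """Per-subject reading measures.

    One row per subject with mean first-fixation durations on the pre-target
    and target words per condition, target total gaze and refixation
    likelihood per condition, and reading speed from congruent sentences.
    """
    out: dict[int, dict] = {}
    for offset, name in ((-1, "pretarget"), (0, "target")):
        ffd = first_fixation_durations(events, offset)
        m = ffd.pivot_table(
            index="subject_id", columns="condition", values="duration_ms",
            aggfunc="mean",
        )
        for cond in m.columns:
            for sid, v in m[cond].items():
                out.setdefault(int(sid), {})[f"ffd_{name}_{cond}_ms"] = float(v)
    gaze = total_gaze_and_refixation(events, 0)
    g = gaze.groupby(["subject_id", "condition"]).agg(
        total_gaze_ms=("total_gaze_ms", "mean"),
        refixation_likelihood=("refixation", "mean"),
    )
    for (sid, cond), row in g.iterrows():
        out.setdefault(int(sid), {})[f"total_gaze_target_{cond}_ms"] = float(
            row["total_gaze_ms"]
        )
        out[int(sid)][f"refixation_target_{cond}"] = float(
            row["refixation_likelihood"]
        )
    speed = reading_speed(events, words_per_sentence)
    for sid, v in speed.items():
        out.setdefault(int(sid), {})["reading_speed_wps"] = float(v)
    df = pd.DataFrame.from_dict(out, orient="index").sort_index()
    df.index.name = "subject_id"
    return df.reset_index()
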