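"""End-to-end orchestration: simulate -> epoch -> coherence -> statistics.

:func:`run_pipeline` executes the full analysis on a (simulated or loaded)
dataset and returns a :class:`RunReport` holding every table the analysis
produces plus the configuration and derived seeds needed to reproduce it.

Stages, mirroring the analysis of a frequency-tagged reading experiment:

1. per subject, cut pre-target fixation epochs ([-0.5, 0.5] s), baseline
   epochs ([0, 1] s from cross-fixation onset) and target epochs;
2. select tagging-response channels by the right-sided permutation test
   (pre-target vs baseline 60 Hz coherence); subjects without any selected
   channel are dropped from downstream contrasts;
3. equalize trial counts between conditions, compute 60 Hz coherence time
   courses per condition over the selected channels, average them within the
   subject's minimum pre-target fixation duration, and contrast the
   conditions with a paired t-test;
4. estimate the onset-latency difference with the leave-one-out jackknife;
5. optionally compute the word-position response curve (offsets -4..+3 vs
   baseline);
6. behavioral summaries, reading speed, and the Spearman correlation between
   the coherence congruency effect and reading speed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, events as ev, spectral, tagstats
from .synth import Dataset, GroundTruth, simulate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

CONDITIONS = ("congruent", "incongruent")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    truth: GroundTruth = field(default_factory=GroundTruth)
    freq_hz: float = 60.0
    halfwidth_hz: float = 5.0
    filter_order: int = 4
    n_perm: int = 5000
    alpha: float = 0.01
    pretarget_window_s: tuple[float, float] = (-0.5, 0.5)
    latency_search_window_s: tuple[float, float] = (-0.15, 0.45)
    curve_average_window_s: tuple[float, float] = (0.0, 0.2)
    candidate_channels: tuple[int, ...] | None = None
    compute_response_curve: bool = True
    seed: int = 0


@dataclass
class RunReport:
    """All results of one pipeline run, with full provenance."""

    config: RunConfig
    selection: pd.DataFrame          # per subject x channel permutation table
    retained_subjects: list[int]
    magnitude: pd.DataFrame          # per-subject condition coherence means
    magnitude_test: dict             # paired t on incongruent vs congruent
    latency: tagstats.LatencyEstimate | None
    response_curve: pd.DataFrame | None
    behavioral: pd.DataFrame
    ffd_tests: pd.DataFrame          # pre-target and target FFD paired tests
    correlation: dict                # Spearman rho/p of coh diff vs speed
    seeds: dict                      # derived per-stage seeds

    @property
    def coherence_difference(self) -> pd.Series:
        """Per-subject incongruent - congruent pre-target coherence."""
        m = self.magnitude.set_index("subject_id")
        return m["incongruent"] - m["congruent"]


def _derive_seeds(master: int, subject_ids) -> dict:
    """Counter-based per-stage seed derivation from the master seed."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(2 * len(subject_ids))
    seeds = {}
    for i, sid in enumerate(subject_ids):
        seeds[("selection", sid)] = children[2 * i]
        seeds[("equalize", sid)] = children[2 * i + 1]
    return seeds


def _subject_condition_curves(
    pretarget: ev.EpochSet,
    channels: np.ndarray,
    eq_seed,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Equalized per-condition coherence curves and fixation durations.

    ``pretarget`` holds precomputed analytic epochs at the tagging frequency.
    """
    eps_c = pretarget.by_condition("congruent")
    eps_i = pretarget.by_condition("incongruent")
    eps_c, eps_i = tagstats.equalize_trials(eps_c, eps_i, seed=eq_seed)
    curves, durations = {}, {}
    for cond, eps in (("congruent", eps_c), ("incongruent", eps_i)):
        coh = spectral.coherence_over_trials(
            eps.sensor[:, channels, :], eps.photodiode
        )
        curves[cond] = coh.mean(axis=0)  # average channels -> (n_samples,)
        durations[cond] = eps.meta["duration_ms"].to_numpy()
    return curves, durations


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> RunReport:
    """Run the full analysis; simulates the dataset from config if not given."""
    if dataset is None:
        dataset = simulate_dataset(config.truth)
    truth = dataset.truth
    events = ev.events_to_frame(dataset.events)
    subject_ids = dataset.subject_ids
    seeds = _derive_seeds(config.seed, subject_ids)

    offsets = range(-4, 4) if config.compute_response_curve else (-1,)
    selection_rows = []
    retained: list[int] = []
    selected_channels: dict[int, np.ndarray] = {}
    per_position_values: dict[object, dict[int, float]] = {}
    curves: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    magnitude_rows = []
    times = None

    for sid in subject_ids:
        # filter-Hilbert once per subject on the continuous recordings, then
        # slice analytic epochs (no per-epoch filtering, no epoch-edge ringing)
        recs = spectral.analytic_recordings(
            dataset.recordings[sid],
            config.freq_hz,
            config.halfwidth_hz,
            config.filter_order,
        )
        sub_events = events[events["subject_id"] == sid]
        epoch_dict: dict[object, ev.EpochSet] = {}
        for off in offsets:
            epoch_dict[off] = ev.extract_epochs(
                recs, sub_events, off, window_s=config.pretarget_window_s
            )
        epoch_dict["baseline"] = ev.extract_baseline_epochs(recs)

        pretarget = epoch_dict[-1]
        baseline = epoch_dict["baseline"]
        if len(pretarget) < 2 or len(baseline) < 2:
            logger.warning("subject %d: too few epochs; excluded", sid)
            continue
        sel = tagstats.permutation_select_sensors(
            pretarget,
            baseline,
            candidate_channels=config.candidate_channels,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=seeds[("selection", sid)],
            freq_hz=config.freq_hz,
            halfwidth_hz=config.halfwidth_hz,
            order=config.filter_order,
            precomputed_analytic=True,
        )
        tab = sel.table.copy()
        tab.insert(0, "subject_id", sid)
        selection_rows.append(tab)
        chans = sel.selected_channels
        if chans.size == 0:
            logger.info("subject %d: no tagging-response channels; dropped", sid)
            continue
        selected_channels[sid] = chans
        retained.append(sid)
        if config.compute_response_curve:
            for pos, val in spectral.position_coherence(
                epoch_dict, chans,
                average_window_s=config.curve_average_window_s,
                precomputed_analytic=True,
            ).items():
                per_position_values.setdefault(pos, {})[sid] = val

        sub_curves, durations = _subject_condition_curves(
            pretarget, chans, seeds[("equalize", sid)]
        )
        times = pretarget.times
        mags = tagstats.mean_coherence_in_min_fixation_window(
            sub_curves, times, durations, truth.sample_rate_hz
        )
        magnitude_rows.append(
            {"subject_id": sid,
             "congruent": mags["congruent"],
             "incongruent": mags["incongruent"],
             "min_fixation_ms": float(
                 np.concatenate(list(durations.values())).min()
             )}
        )
        for cond in CONDITIONS:
            curves[cond].append(sub_curves[cond])

    selection = (
        pd.concat(selection_rows, ignore_index=True)
        if selection_rows
        else pd.DataFrame(columns=["subject_id", "channel", "z", "p_perm", "selected"])
    )
    magnitude = pd.DataFrame(magnitude_rows)

    if len(magnitude) >= 3:
        t, p, d = tagstats.paired_condition_test(
            magnitude["incongruent"], magnitude["congruent"]
        )
        magnitude_test = {
            "t": t, "p": p, "cohens_d": d, "n_subjects": int(len(magnitude)),
            "mean_difference": float(
                (magnitude["incongruent"] - magnitude["congruent"]).mean()
            ),
        }
    else:
        magnitude_test = {"t": np.nan, "p": np.nan, "cohens_d": np.nan,
                          "n_subjects": int(len(magnitude)),
                          "mean_difference": np.nan}

    latency = None
    if len(retained) >= 3:
        try:
            latency = tagstats.jackknife_latency_difference(
                {c: np.stack(curves[c]) for c in CONDITIONS},
                times,
                search_window=config.latency_search_window_s,
            )
        except ValueError as err:
            logger.warning("latency estimation failed: %s", err)

    response_curve = None
    if config.compute_response_curve and retained:
        response_curve = spectral.response_curve_table(per_position_values)

    behavioral = behavior.behavioral_summary(events, truth.words_per_sentence)
    ffd_tests = pd.DataFrame(
        [behavior.paired_ffd_test(events, off) for off in (-1, 0)]
    )

    correlation = {"rho": np.nan, "p": np.nan, "n_subjects": len(retained)}
    if len(magnitude) >= 5:
        speed = behavior.reading_speed(events, truth.words_per_sentence)
        m = magnitude.set_index("subject_id")
        sids = [s for s in m.index if s in speed.index]
        diff = (m.loc[sids, "incongruent"] - m.loc[sids, "congruent"]).to_numpy()
        try:
            rho, p = behavior.speed_coherence_correlation(
                diff, speed.loc[sids].to_numpy()
            )
            correlation = {"rho": rho, "p": p, "n_subjects": len(sids)}
        except ValueError as err:
            logger.warning("correlation undefined: %s", err)

    return RunReport(
        config=config,
        selection=selection,
        retained_subjects=retained,
        magnitude=magnitude,
        magnitude_test=magnitude_test,
        latency=latency,
        response_curve=response_curve,
        behavioral=behavioral,
        ffd_tests=ffd_tests,
        correlation=correlation,
        seeds={f"{stage}/subject{sid}": repr(seq)
               for (stage, sid), seq in seeds.items()},
    )


def _config_lines(config: RunConfig) -> list[str]:
    lines = ["[config]"]
    for f in dataclasses.fields(RunConfig):
        if f.name == "truth":
            continue
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    lines.append("[ground truth]")
    for f in dataclasses.fields(GroundTruth):
        lines.append(f"{f.name} = {getattr(config.truth, f.name)}")
    return lines


def write_report(report: RunReport, outdir, figures: bool = False) -> Path:
    """Emit TSV tables plus a plain-text run summary; returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.selection.to_csv(outdir / "sensor_selection.tsv", sep="\t", index=False)
    report.magnitude.to_csv(outdir / "pretarget_coherence.tsv", sep="\t", index=False)
    report.behavioral.to_csv(outdir / "behavioral_summary.tsv", sep="\t", index=False)
    report.ffd_tests.to_csv(outdir / "ffd_tests.tsv", sep="\t", index=False)
    if report.response_curve is not None:
        report.response_curve.to_csv(
            outdir / "response_curve.tsv", sep="\t", index=False
        )

    lines = ["# riftpipe run report", ""]
    lines += _config_lines(report.config)
    lines.append("[seeds]")
    for k, v in report.seeds.items():
        lines.append(f"{k} = {v}")
    lines.append("")
    lines.append("[results]")
    lines.append(f"retained_subjects = {report.retained_subjects}")
    mt = report.magnitude_test
    lines.append(
        "pretarget_coherence: mean diff (incongruent - congruent) = "
        f"{mt['mean_difference']:.5f}, t({mt['n_subjects'] - 1}) = {mt['t']:.3f}, "
        f"p = {mt['p']:.4f}, d = {mt['cohens_d']:.3f}"
    )
    if report.latency is not None:
        lat = report.latency
        lines.append(
            f"onset latency: congruent {lat.latency_congruent_ms:.1f} ms, "
            f"incongruent {lat.latency_incongruent_ms:.1f} ms, "
            f"difference {lat.difference_ms:.1f} ms, S_D {lat.jackknife_sd:.2f} ms, "
            f"t({lat.n_subjects - 1}) = {lat.t_value:.3f}, p = {lat.p_value:.4f}"
        )
    else:
        lines.append("onset latency: not estimated")
    for _, row in report.ffd_tests.iterrows():
        which = "pre-target" if row["word_offset"] == -1 else "target"
        lines.append(
            f"first fixation ({which}): incongruent {row['mean_incongruent_ms']:.1f}"
            f" ms vs congruent {row['mean_congruent_ms']:.1f} ms, "
            f"t = {row['t']:.3f}, p = {row['p']:.4g}"
        )
    corr = report.correlation
    lines.append(
        f"speed-coherence Spearman rho = {corr['rho']:.3f}, p = {corr['p']:.4f} "
        f"(n = {corr['n_subjects']})"
    )
    if report.response_curve is not None:
        nonbase = report.response_curve[
            report.response_curve["position"] != "baseline"
        ]
        if not nonbase.empty:
            peak = nonbase.loc[nonbase["mean_coherence"].idxmax(), "position"]
            lines.append(f"response curve peak at word offset {peak}")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")

    if figures:
        _write_figures(report, outdir)
    return path


def _write_figures(report: RunReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.response_curve is not None:
        rc = report.response_curve
        nonbase = rc[rc["position"] != "baseline"]
        base = rc[rc["position"] == "baseline"]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.errorbar(
            nonbase["position"], nonbase["mean_coherence"], yerr=nonbase["sem"],
            marker="o",
        )
        if not base.empty:
            ax.axhline(base["mean_coherence"].iloc[0], ls="--", color="grey",
                       label="baseline")
            ax.legend()
        ax.set_xlabel("word offset relative to target")
        ax.set_ylabel("60 Hz coherence")
        fig.tight_layout()
        fig.savefig(outdir / "response_curve.png", dpi=150)
        plt.close(fig)

    if not report.magnitude.empty:
        fig, ax = plt.subplots(figsize=(4, 3.5))
        m = report.magnitude
        ax.violinplot([m["congruent"], m["incongruent"]], showmeans=True)
        ax.set_xticks([1, 2], ["congruent", "incongruent"])
        ax.set_ylabel("pre-target 60 Hz coherence")
        fig.tight_layout()
        fig.savefig(outdir / "pretarget_coherence.png", dpi=150)
        plt.close(fig)
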