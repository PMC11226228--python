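"""Tagging-response statistics: sensor selection, contrasts, onset latencies.

Three statistical pieces sit here:

* **Sensor selection.**  A channel is a tagging-response channel if its 60 Hz
  sensor-photodiode coherence during pre-target fixations exceeds that of the
  no-flicker baseline interval.  The coherence difference is converted to a
  z-statistic via Fisher's atanh with a trial-count bias term
  ``bias = 1/(2n - 2)`` per condition, and its significance is assessed with a
  Monte-Carlo permutation test that shuffles epoch labels between the two
  conditions (right-sided, alpha = 0.01, 5000 shuffles by default).

* **Condition contrasts.**  Trial counts are equalized between congruent and
  incongruent conditions by random subsampling; 60 Hz coherence is averaged
  over the selected channels and over each subject's minimum pre-target
  fixation duration (so no post-fixation signal leaks in), then compared with
  a two-sided paired t-test.

* **Onset latency.**  The latency of the coherence time course is the first
  time it reaches half-maximum, ``cohmin + (cohmax - cohmin)/2``, with linear
  interpolation.  The group-level condition difference gets its standard error
  from a leave-one-subject-out jackknife:
  ``S_D = sqrt(((n-1)/n) * sum_i (D_-i - Jbar)^2)``, and
  ``t = D_overall / S_D`` with n-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .events import EpochSet
from .spectral import EDGE_TRIM_S, _analytic, _normalize_photodiode, design_bandpass

__all__ = [
    "SensorSelection",
    "LatencyEstimate",
    "coherence_bias",
    "z_coherence_diff",
    "permutation_select_sensors",
    "equalize_trials",
    "min_fixation_window",
    "mean_coherence_in_min_fixation_window",
    "paired_condition_test",
    "half_max_latency",
    "jackknife_latency_difference",
]


@dataclass
class SensorSelection:
    """Per-channel permutation result.  ``selected`` ⇔ p_perm < alpha."""

    table: pd.DataFrame  # columns: channel, z, p_perm, selected
    n_perm: int
    alpha: float
    side: str = "right"

    @property
    def selected_channels(self) -> np.ndarray:
        return self.table.loc[self.table["selected"], "channel"].to_numpy()


@dataclass
class LatencyEstimate:
    """Group-level half-maximum onset latencies and their jackknife contrast."""

    latency_congruent_ms: float
    latency_incongruent_ms: float
    difference_ms: float          # incongruent - congruent (positive = delayed)
    jackknife_sd: float           # S_D, in ms
    t_value: float
    p_value: float
    n_subjects: int
    leave_one_out_differences_ms: np.ndarray


def coherence_bias(n: int) -> float:
    """Trial-count bias of Fisher-transformed coherence: 1 / (2n - 2)."""
    if n < 2:
        raise ValueError(f"need at least 2 trials, got {n}")
    return 1.0 / (2.0 * n - 2.0)


def z_coherence_diff(coh1: float, n1: int, coh2: float, n2: int) -> float:
    """Bias-corrected z for a coherence difference between two conditions.

    z = [(atanh|coh1| - bias1) - (atanh|coh2| - bias2)] / sqrt(bias1 + bias2),
    with bias_i = 1/(2 n_i - 2).  The denominator is the square root of the
    summed bias terms (the variance of the difference).
    """
    coh1, coh2 = abs(float(coh1)), abs(float(coh2))
    if coh1 >= 1.0 or coh2 >= 1.0:
        raise ValueError(
            "coherence of 1 gives infinite atanh; clip inputs at 1 - 1e-10"
        )
    b1, b2 = coherence_bias(n1), coherence_bias(n2)
    return ((np.arctanh(coh1) - b1) - (np.arctanh(coh2) - b2)) / np.sqrt(b1 + b2)


# ---------------------------------------------------------------------------
# permutation sensor selection


def _time_mean_coherence_perms(
    cross: np.ndarray,
    px: np.ndarray,
    py_sums: tuple[np.ndarray, np.ndarray],
    member: np.ndarray,
    complement: np.ndarray,
    t_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged coherence of each epoch partition and its complement.

    ``cross``/``px``: per-epoch sensor-photodiode cross-products and squared
    sensor magnitudes for one channel, shape (n_epochs, n_samples);
    ``py_sums``: the photodiode power sums (partition, complement) shared by
    all channels; ``member``/``complement``: (n_part, n_epochs) 0/1 rows.
    Returns two (n_part,) arrays.
    """
    s1 = member @ cross.astype(np.complex64, copy=False)
    s2 = complement @ cross.astype(np.complex64, copy=False)
    px = px.astype(np.float32, copy=False)
    d1 = (member @ px) * py_sums[0]
    d2 = (complement @ px) * py_sums[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = np.where(d1 > 0, np.abs(s1) ** 2 / d1, np.nan)
        c2 = np.where(d2 > 0, np.abs(s2) ** 2 / d2, np.nan)
    return (
        np.nanmean(c1[:, t_mask], axis=1),
        np.nanmean(c2[:, t_mask], axis=1),
    )


def permutation_select_sensors(
    pretarget: EpochSet,
    baseline: EpochSet,
    candidate_channels=None,
    n_perm: int = 5000,
    alpha: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
    freq_hz: float = 60.0,
    halfwidth_hz: float = 5.0,
    order: int = 4,
    precomputed_analytic: bool = False,
) -> SensorSelection:
    """Select channels with stronger tagging coherence than baseline.

    Per candidate channel the empirical z (see :func:`z_coherence_diff`) is
    computed from the time-averaged 60 Hz coherence of the pre-target and
    baseline epoch sets; a null distribution comes from recomputing z after
    shuffling epoch labels between the pooled sets (a shared shuffle across
    channels), and ``p_perm = (1 + #{z_null >= z_obs}) / (1 + n_perm)``.
    Right-sided: only a coherence increase counts.  Reproducible from seed.

    With ``precomputed_analytic`` the epoch sets are taken to hold complex
    analytic samples already (see :func:`riftpipe.spectral.analytic_recordings`)
    and the filter-Hilbert step is skipped.
    """
    import warnings

    if len(pretarget) < 2 or len(baseline) < 2:
        raise ValueError("need at least 2 epochs per condition")
    if pretarget.n_samples != baseline.n_samples:
        raise ValueError("pre-target and baseline epochs must have equal length")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    channels = (
        np.arange(pretarget.n_channels)
        if candidate_channels is None
        else np.asarray(candidate_channels, dtype=int)
    )
    if channels.size == 0:
        raise ValueError("empty candidate channel set")

    n1, n2 = len(pretarget), len(baseline)
    rng = np.random.default_rng(seed)
    if precomputed_analytic:
        ax = np.concatenate(
            [pretarget.sensor[:, channels, :], baseline.sensor[:, channels, :]],
            axis=0,
        ).astype(np.complex64)
        ay = np.concatenate(
            [pretarget.photodiode, baseline.photodiode], axis=0
        ).astype(np.complex64)[:, None, :]
    else:
        # analytic signals of the pooled epochs at the tagging frequency
        sos = design_bandpass(
            freq_hz, pretarget.sample_rate_hz, halfwidth_hz, order
        )
        sens = np.concatenate(
            [pretarget.sensor[:, channels, :], baseline.sensor[:, channels, :]],
            axis=0,
        ).astype(np.float32)
        photo = np.concatenate(
            [
                _normalize_photodiode(pretarget.photodiode),
                _normalize_photodiode(baseline.photodiode),
            ],
            axis=0,
        ).astype(np.float32)
        ax = _analytic(sens, sos).astype(np.complex64)
        ay = _analytic(photo, sos).astype(np.complex64)[:, None, :]
    cross = ax * np.conj(ay)               # (n_ep, n_ch, T)
    px = np.abs(ax) ** 2
    py = np.abs(ay[:, 0, :]) ** 2          # (n_ep, T), shared by all channels

    n_samp = pretarget.n_samples
    trim = int(round(EDGE_TRIM_S * pretarget.sample_rate_hz))
    if n_samp <= 2 * trim + 1:  # epoch too short to spare the edges
        trim = 0
    t_mask = np.zeros(n_samp, dtype=bool)
    t_mask[trim : n_samp - trim if trim else n_samp] = True

    # observed + permuted membership rows (row 0 = the observed labelling)
    member = np.empty((n_perm + 1, n1 + n2), dtype=np.float32)
    member[0] = np.concatenate([np.ones(n1), np.zeros(n2)])
    for i in range(1, n_perm + 1):
        member[i] = member[0][rng.permutation(n1 + n2)]
    complement = np.float32(1.0) - member
    py = py.astype(np.float32, copy=False)
    py_sums = (member @ py, complement @ py)

    b1, b2 = coherence_bias(n1), coherence_bias(n2)
    eps = 1e-10
    z_obs = np.empty(channels.size)
    p_perm = np.empty(channels.size)
    for ci in range(channels.size):
        c1, c2 = _time_mean_coherence_perms(
            cross[:, ci, :], px[:, ci, :], py_sums, member, complement, t_mask
        )
        c1 = np.clip(c1, 0.0, 1.0 - eps)
        c2 = np.clip(c2, 0.0, 1.0 - eps)
        z = ((np.arctanh(c1) - b1) - (np.arctanh(c2) - b2)) / np.sqrt(b1 + b2)
        z_obs[ci] = z[0]
        if not np.isfinite(z[0]):
            p_perm[ci] = 1.0
        else:
            p_perm[ci] = (1.0 + np.sum(z[1:] >= z[0])) / (1.0 + n_perm)
    table = pd.DataFrame(
        {
            "channel": channels,
            "z": z_obs,
            "p_perm": p_perm,
            "selected": p_perm < alpha,
        }
    )
    return SensorSelection(table=table, n_perm=n_perm, alpha=alpha)


# ---------------------------------------------------------------------------
# condition contrasts


def equalize_trials(
    epochs_a: EpochSet, epochs_b: EpochSet, seed: int | np.random.SeedSequence = 0
) -> tuple[EpochSet, EpochSet]:
    """Randomly discard surplus epochs so both sets have equal counts."""
    if len(epochs_a) == 0 or len(epochs_b) == 0:
        raise ValueError("both epoch sets must be nonempty")
    n = min(len(epochs_a), len(epochs_b))
    rng = np.random.default_rng(seed)
    out = []
    for eps in (epochs_a, epochs_b):
        if len(eps) == n:
            out.append(eps)
        else:
            keep = np.sort(rng.choice(len(eps), size=n, replace=False))
            out.append(eps.subset(keep))
    return out[0], out[1]


def min_fixation_window(durations_ms: np.ndarray) -> tuple[float, float]:
    """[0, d_min] averaging window from pooled first-fixation durations (ms)."""
    durations_ms = np.asarray(durations_ms, dtype=float)
    if durations_ms.size == 0:
        raise ValueError("no fixation durations given")
    return (0.0, float(durations_ms.min()) / 1000.0)


def mean_coherence_in_min_fixation_window(
    coh_by_condition: dict[str, np.ndarray],
    times: np.ndarray,
    durations_ms_by_condition: dict[str, np.ndarray],
    sample_rate_hz: float = 1000.0,
) -> dict[str, float]:
    """Average each condition's coherence curve over [0, min fixation duration].

    The window end is the minimum pre-target first-fixation duration pooled
    over both conditions, so the average never includes samples after the
    shortest fixation ended (no contamination from target-fixation signal).
    """
    pooled = np.concatenate([np.asarray(d, float) for d in
                             durations_ms_by_condition.values()])
    lo, hi = min_fixation_window(pooled)
    times = np.asarray(times)
    mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError(
            f"minimum-fixation window [{lo}, {hi}] s spans fewer than 2 samples"
        )
    return {
        cond: float(np.nanmean(np.asarray(curve)[mask]))
        for cond, curve in coh_by_condition.items()
    }


def paired_condition_test(
    values_incongruent, values_congruent
) -> tuple[float, float, float]:
    """Two-sided paired t-test plus Cohen's d of the paired difference.

    Returns (t, p, d).  Zero variance of the differences is flagged with
    t = ±inf (p = 0) unless the differences are all zero (t = 0, p = 1).
    """
    a = np.asarray(values_incongruent, dtype=float)
    b = np.asarray(values_congruent, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired samples with n >= 3")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, 1.0, 0.0
        return float(np.sign(diff.mean()) * np.inf), 0.0, float(np.inf)
    t, p = scipy.stats.ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return float(t), float(p), d


# ---------------------------------------------------------------------------
# onset latency


def half_max_latency(
    times: np.ndarray,
    curve: np.ndarray,
    search_window: tuple[float, float] = (0.0, 0.5),
) -> float:
    """First time the curve reaches cohmin + (cohmax - cohmin)/2.

    cohmin/cohmax are taken within the search window; the latency is the time
    of the earliest sample at or above the half-maximum level (so a step at
    100 ms has latency exactly 100 ms, and a 0-100 ms linear ramp sampled on
    the grid has latency exactly 50 ms).  Ties across several samples resolve
    to the earliest.  A constant curve has no latency.
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    mask = (times >= search_window[0] - 1e-12) & (times <= search_window[1] + 1e-12)
    t = times[mask]
    c = curve[mask]
    ok = np.isfinite(c)
    t, c = t[ok], c[ok]
    if t.size < 2 or np.ptp(c) == 0:
        raise ValueError("curve is constant within the search window; "
                         "half-maximum latency is undefined")
    level = c.min() + (c.max() - c.min()) / 2.0
    return float(t[np.flatnonzero(c >= level)[0]])


def jackknife_latency_difference(
    curves_by_condition: dict[str, np.ndarray],
    times: np.ndarray,
    search_window: tuple[float, float] = (0.0, 0.5),
) -> LatencyEstimate:
    """Leave-one-subject-out jackknife of the onset-latency condition contrast.

    ``curves_by_condition`` maps "congruent"/"incongruent" to (n_subjects,
    n_samples) coherence curves (same subject order).  The group difference
    D = latency(incongruent) - latency(congruent) is computed from the
    all-subject average curves; each leave-one-out difference D_-i from the
    remaining subjects' averages; S_D = sqrt(((n-1)/n) * sum (D_-i - Jbar)^2);
    t = D / S_D with n-1 degrees of freedom (two-tailed).
    """
    cong = np.asarray(curves_by_condition["congruent"], dtype=float)
    incong = np.asarray(curves_by_condition["incongruent"], dtype=float)
    if cong.shape != incong.shape:
        raise ValueError("condition curve arrays must have matching shapes")
    n = cong.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for the jackknife")

    def _lat(curve, label):
        try:
            return half_max_latency(times, curve, search_window)
        except ValueError as err:
            raise ValueError(f"undefined latency for {label}: {err}") from err

    lat_c = _lat(cong.mean(axis=0), "congruent (all subjects)") * 1000.0
    lat_i = _lat(incong.mean(axis=0), "incongruent (all subjects)") * 1000.0
    overall = lat_i - lat_c

    d_loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        li = _lat(incong[keep].mean(axis=0), f"incongruent (without subject {i})")
        lc = _lat(cong[keep].mean(axis=0), f"congruent (without subject {i})")
        d_loo[i] = (li - lc) * 1000.0
    jbar = d_loo.mean()
    s_d = float(np.sqrt((n - 1) / n * np.sum((d_loo - jbar) ** 2)))
    if s_d == 0:
        t = 0.0 if overall == 0 else float(np.sign(overall) * np.inf)
    else:
        t = float(overall / s_d)
    p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 1)) if np.isfinite(t) else 0.0
    return LatencyEstimate(
        latency_congruent_ms=lat_c,
        latency_incongruent_ms=lat_i,
        difference_ms=float(overall),
        jackknife_sd=s_d,
        t_value=t,
        p_value=p,
        n_subjects=n,
        leave_one_out_differences_ms=d_loo,
    )
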