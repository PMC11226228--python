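"""Synthetic rapid-invisible-frequency-tagging (RIFT) reading experiments.

Generates complete frequency-tagged natural-reading datasets with known ground
truth: a photodiode reference carrying a clean 60 Hz tagging sinusoid, sensor
channels in which the tagging component is modulated by an attention envelope
tied to the currently fixated word, fixation-event tables with a congruency
effect on target first-fixation durations, and 1/f + white sensor noise.

The generative model, briefly: during reading, covert attention to the
flickered target word waxes and wanes with eye position.  The 60 Hz tagging
amplitude on the "tagged" sensor channels at time t equals

    snr * envelope(word offset fixated at t) * condition_factor,

where the envelope peaks at the pre-target word (offset -1) and the condition
factor (an amplitude reduction plus an onset delay of the ramp to the
pre-target level) applies only within pre-target fixation intervals of
incongruent trials.  Before sentence onset (the baseline interval) no tagging
component is present in any sensor channel, while the photodiode flickers
throughout the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FlickerSpec",
    "GroundTruth",
    "TrialRecording",
    "FixationEvent",
    "Dataset",
    "DEFAULT_ATTENTION_ENVELOPE",
    "gaussian_mask",
    "flicker_luminance",
    "simulate_fixation_sequence",
    "simulate_subject",
    "simulate_dataset",
    "pink_white_noise",
]

#: Relative tagging gain per word offset (target = 0), peaking at the
#: pre-target word.  Left-skewed: attention is allocated to the flickered
#: word up to ~3 words before it is fixated, and decays quickly afterwards.
DEFAULT_ATTENTION_ENVELOPE: Mapping[int, float] = {
    -4: 0.0, -3: 0.2, -2: 0.45, -1: 1.0, 0: 0.75, 1: 0.25, 2: 0.0, 3: 0.0,
}


@dataclass(frozen=True)
class FlickerSpec:
    """Parameters of the luminance flicker applied to the target word patch."""

    tagging_frequency_hz: float = 60.0
    mask_sigma_deg: float = 0.02
    luminance_range: tuple[float, float] = (0.0, 1.0)
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tagging_frequency_hz < self.sample_rate_hz / 2:
            raise ValueError(
                "tagging_frequency_hz must lie in (0, Nyquist); got "
                f"{self.tagging_frequency_hz} at fs={self.sample_rate_hz}"
            )
        if self.mask_sigma_deg <= 0:
            raise ValueError("mask_sigma_deg must be > 0")
        lo, hi = self.luminance_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("luminance_range must satisfy 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True effect parameters of a simulated experiment.

    ``snr`` is the ratio of the (envelope-peak) 60 Hz tagging amplitude to the
    sensor noise standard deviation on tagged channels.  ``attention_envelope``
    maps word offsets relative to the target (-4..+3) to relative tagging gain
    and must peak at the pre-target word (offset -1).
    """

    amplitude_factor_incongruent: float = 0.8
    latency_shift_ms: float = 25.0
    attention_envelope: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENTION_ENVELOPE)
    )
    target_ffd_effect_ms: float = 30.0
    snr: float = 0.15
    n_channels: int = 24
    n_tagged_channels: int = 6
    fixation_mean_ms: float = 200.0
    fixation_sd_ms: float = 70.0
    n_trials_per_condition: int = 80
    n_subjects: int = 34
    words_per_sentence: int = 12
    sample_rate_hz: float = 1000.0
    tagging_frequency_hz: float = 60.0
    saccade_ms: float = 30.0
    ramp_ms: float = 50.0
    refixation_prob: float = 0.10
    baseline_s: float = 1.2
    pre_cross_s: float = 0.5   # recording before the fixation cross appears
    pink_fraction: float = 0.5
    subject_speed_multipliers: Sequence[float] | None = None
    amplitude_factor_by_subject: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_factor_incongruent <= 1.0:
            raise ValueError("amplitude_factor_incongruent must be in (0, 1]")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.fixation_sd_ms < 0:
            raise ValueError("fixation_sd_ms must be >= 0")
        if min(self.n_channels, self.n_tagged_channels, self.n_trials_per_condition,
               self.n_subjects, self.words_per_sentence) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_tagged_channels > self.n_channels:
            raise ValueError("n_tagged_channels cannot exceed n_channels")
        if self.words_per_sentence < 8:
            raise ValueError(
                "words_per_sentence must be >= 8 so offsets -4..+3 exist"
            )
        env = dict(self.attention_envelope)
        if any(v < 0 for v in env.values()):
            raise ValueError("attention envelope values must be >= 0")
        if env and max(env, key=env.get) != -1:
            raise ValueError("attention envelope must peak at offset -1")

    @property
    def target_word_index(self) -> int:
        """1-based target position: mid-sentence, with offsets -4..+3 in range."""
        return max(5, min(self.words_per_sentence - 3, self.words_per_sentence // 2 + 1))

    def envelope_at(self, offset: int | None) -> float:
        if offset is None:
            return 0.0
        return float(dict(self.attention_envelope).get(int(offset), 0.0))


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: where, when and for how long the eyes landed."""

    trial_id: int
    subject_id: int
    word_index: int            # 1-based position in the sentence
    word_offset: int | None    # position relative to the target, -4..+3, else None
    onset_sample: int          # 0-based sample index into the trial recording
    duration_ms: float
    pass_index: int            # 1 = first-pass reading
    condition: str             # "congruent" | "incongruent"


@dataclass
class TrialRecording:
    """Multichannel sensor data + photodiode reference for one sentence trial."""

    trial_id: int
    subject_id: int
    condition: str
    sensor_data: np.ndarray       # (n_channels, n_samples)
    photodiode: np.ndarray        # (n_samples,) normalized luminance
    sample_rate_hz: float
    cross_fixation_onset_sample: int
    sentence_onset_sample: int

    def __post_init__(self) -> None:
        if self.photodiode.shape[0] != self.sensor_data.shape[1]:
            raise ValueError("photodiode length must equal sensor sample count")
        if not self.cross_fixation_onset_sample < self.sentence_onset_sample:
            raise ValueError("cross-fixation onset must precede sentence onset")

    @property
    def n_samples(self) -> int:
        return self.sensor_data.shape[1]


@dataclass
class Dataset:
    """A full simulated experiment: recordings per subject + events + truth."""

    recordings: dict[int, list[TrialRecording]]
    events: list[FixationEvent]
    truth: GroundTruth

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.recordings)


# ---------------------------------------------------------------------------
# stimulus-side closed forms


def gaussian_mask(x, y, sigma: float):
    """Transparency of the smoothing mask at visual-degree coordinates (x, y).

    mask = exp(-x^2 / (2 sigma^2) - y^2 / (2 sigma^2)); 1 at the patch centre.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.exp(-(x ** 2) / (2 * sigma ** 2) - (y ** 2) / (2 * sigma ** 2))
    return out if out.ndim else float(out)


def flicker_luminance(t, spec: FlickerSpec = FlickerSpec(), phase: float = 0.0):
    """Normalized patch luminance at time ``t`` seconds.

    A sinusoid at the tagging frequency spanning ``spec.luminance_range``,
    whose time-average is mid-grey (0.5 for the default full range).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lo, hi = spec.luminance_range
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    out = mid + half * np.sin(2 * np.pi * spec.tagging_frequency_hz * t + phase)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# noise


def pink_white_noise(
    n_samples: int,
    size: int,
    rng: np.random.Generator,
    pink_fraction: float = 0.5,
    std: float = 1.0,
) -> np.ndarray:
    """(size, n_samples) rows of unit-variance 1/f + white noise, scaled by std.

    The pink part is spectrally shaped white noise (amplitude ∝ 1/sqrt(f)),
    normalized to unit variance before mixing, so the mixture has variance
    ``std**2`` regardless of ``pink_fraction``.
    """
    white = rng.standard_normal((size, n_samples))
    if pink_fraction <= 0:
        return std * white
    spec = np.fft.rfft(rng.standard_normal((size, n_samples)), axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # unit d: shape only matters
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    out = np.sqrt(pink_fraction) * pink + np.sqrt(1.0 - pink_fraction) * white
    return std * out


# ---------------------------------------------------------------------------
# fixation sequences


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    var = sd ** 2
    sigma2 = np.log1p(var / mean ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_duration(rng, mean_ms: float, sd_ms: float) -> float:
    if sd_ms == 0:
        return float(mean_ms)
    mu, sig = _lognormal_params(mean_ms, sd_ms)
    return float(rng.lognormal(mu, sig))


def simulate_fixation_sequence(
    truth: GroundTruth,
    trial_id: int,
    condition: str,
    rng: np.random.Generator,
    subject_id: int = 0,
    speed_multiplier: float = 1.0,
    sentence_onset_sample: int = 0,
) -> list[FixationEvent]:
    """One trial's first-pass fixations, one per word, in reading order.

    Durations are lognormal with the configured mean/sd (divided by the
    subject's speed multiplier); incongruent target first fixations get
    ``target_ffd_effect_ms`` added to the mean.  With probability
    ``refixation_prob`` a single second-pass fixation on a random earlier word
    is appended after the last word.
    """
    if condition not in ("congruent", "incongruent"):
        raise ValueError(f"unknown condition {condition!r}")
    if truth.fixation_sd_ms < 0:
        raise ValueError("fixation_sd_ms must be >= 0")
    fs = truth.sample_rate_hz
    tgt = truth.target_word_index
    events: list[FixationEvent] = []
    # first fixation lands shortly after sentence onset
    t = sentence_onset_sample + int(round(truth.saccade_ms * fs / 1000.0))
    for w in range(1, truth.words_per_sentence + 1):
        mean = truth.fixation_mean_ms
        if w == tgt and condition == "incongruent":
            mean = mean + truth.target_ffd_effect_ms
        dur = _draw_duration(rng, mean, truth.fixation_sd_ms) / speed_multiplier
        dur = max(dur, 1000.0 / fs)  # at least one sample
        offset = w - tgt
        events.append(
            FixationEvent(
                trial_id=trial_id,
                subject_id=subject_id,
                word_index=w,
                word_offset=offset if -4 <= offset <= 3 else None,
                onset_sample=int(t),
                duration_ms=dur,
                pass_index=1,
                condition=condition,
            )
        )
        t += int(round(dur * fs / 1000.0)) + int(round(truth.saccade_ms * fs / 1000.0))
    if truth.refixation_prob > 0 and rng.random() < truth.refixation_prob:
        w = int(rng.integers(1, truth.words_per_sentence + 1))
        dur = _draw_duration(rng, truth.fixation_mean_ms, truth.fixation_sd_ms)
        dur = max(dur / speed_multiplier, 1000.0 / fs)
        offset = w - tgt
        events.append(
            FixationEvent(
                trial_id=trial_id,
                subject_id=subject_id,
                word_index=w,
                word_offset=offset if -4 <= offset <= 3 else None,
                onset_sample=int(t),
                duration_ms=dur,
                pass_index=2,
                condition=condition,
            )
        )
    return events


# ---------------------------------------------------------------------------
# neural recordings


def _amplitude_envelope(
    truth: GroundTruth,
    fixations: Sequence[FixationEvent],
    n_samples: int,
    condition: str,
    amplitude_factor: float,
) -> np.ndarray:
    """Instantaneous tagging-amplitude gain over one trial.

    Piecewise level per fixation (attention envelope at the fixated word's
    offset), with a linear ramp of ``ramp_ms`` at each level change.  Within
    the pre-target fixation of incongruent trials the level is multiplied by
    the amplitude factor and the ramp onset is delayed by ``latency_shift_ms``.
    Zero before the first fixation (hence zero throughout the baseline).
    """
    fs = truth.sample_rate_hz
    ramp_n = max(1, int(round(truth.ramp_ms * fs / 1000.0)))
    gain = np.zeros(n_samples)
    level = 0.0
    first_pass = [f for f in fixations if f.pass_index == 1]
    for k, fx in enumerate(first_pass):
        target_level = truth.envelope_at(fx.word_offset)
        start = fx.onset_sample
        if fx.word_offset == -1 and condition == "incongruent":
            target_level *= amplitude_factor
            start += int(round(truth.latency_shift_ms * fs / 1000.0))
        end = (
            first_pass[k + 1].onset_sample
            if k + 1 < len(first_pass)
            else n_samples
        )
        if fx.onset_sample >= n_samples:
            break
        # hold the previous level until the (possibly delayed) ramp start
        start = min(start, n_samples)
        gain[fx.onset_sample:start] = level
        ramp_end = min(start + ramp_n, n_samples)
        gain[start:ramp_end] = np.linspace(
            level, target_level, ramp_end - start, endpoint=False
        )
        gain[ramp_end:end] = target_level
        level = target_level
    return gain


def simulate_subject(
    truth: GroundTruth,
    subject_id: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrialRecording], list[FixationEvent]]:
    """Simulate all trials of one subject.

    The photodiode carries the clean tagging sinusoid for the full trial (the
    tracking disk flickers throughout); tagged sensor channels carry the same
    sinusoid scaled by ``snr * gain(t)`` (gain from the attention envelope and
    condition effects) on top of 1/f + white noise of unit standard deviation;
    non-tagged channels are noise only.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(truth.seed).spawn(truth.n_subjects + 1)[subject_id]
        )
    fs = truth.sample_rate_hz
    f0 = truth.tagging_frequency_hz
    speed = 1.0
    if truth.subject_speed_multipliers is not None:
        speed = float(truth.subject_speed_multipliers[subject_id])
    amp_factor = truth.amplitude_factor_incongruent
    if truth.amplitude_factor_by_subject is not None:
        amp_factor = float(truth.amplitude_factor_by_subject[subject_id])

    conditions = ["congruent"] * truth.n_trials_per_condition + [
        "incongruent"
    ] * truth.n_trials_per_condition
    recordings: list[TrialRecording] = []
    all_events: list[FixationEvent] = []
    pre_cross_n = int(round(truth.pre_cross_s * fs))
    baseline_n = int(round(truth.baseline_s * fs))
    tail_n = int(round(0.3 * fs))
    for trial_id, condition in enumerate(conditions):
        cross_onset = pre_cross_n
        sentence_onset = cross_onset + baseline_n
        fixations = simulate_fixation_sequence(
            truth, trial_id, condition, rng,
            subject_id=subject_id,
            speed_multiplier=speed,
            sentence_onset_sample=sentence_onset,
        )
        last = fixations[-1]
        n_samples = (
            last.onset_sample
            + int(round(last.duration_ms * fs / 1000.0))
            + tail_n
        )
        t = np.arange(n_samples) / fs
        # phase 0 at cross-fixation onset
        carrier = np.sin(2 * np.pi * f0 * (t - cross_onset / fs))
        photodiode = 0.5 + 0.5 * carrier
        noise = pink_white_noise(
            n_samples, truth.n_channels, rng, truth.pink_fraction
        )
        sensors = noise
        if truth.snr > 0:
            gain = _amplitude_envelope(
                truth, fixations, n_samples, condition, amp_factor
            )
            sensors[: truth.n_tagged_channels] += truth.snr * gain * carrier
        recordings.append(
            TrialRecording(
                trial_id=trial_id,
                subject_id=subject_id,
                condition=condition,
                sensor_data=sensors,
                photodiode=photodiode,
                sample_rate_hz=fs,
                cross_fixation_onset_sample=cross_onset,
                sentence_onset_sample=sentence_onset,
            )
        )
        all_events.extend(fixations)
    return recordings, all_events


def simulate_dataset(truth: GroundTruth) -> Dataset:
    """Simulate ``n_subjects`` independent subjects; reproducible from seed."""
    recordings: dict[int, list[TrialRecording]] = {}
    events: list[FixationEvent] = []
    seqs = np.random.SeedSequence(truth.seed).spawn(truth.n_subjects + 1)
    for sid in range(truth.n_subjects):
        rng = np.random.default_rng(seqs[sid])
        recs, evs = simulate_subject(truth, sid, rng)
        recordings[sid] = recs
        events.extend(evs)
    return Dataset(recordings=recordings, events=events, truth=truth)
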