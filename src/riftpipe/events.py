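"""Reading measures from fixation events and fixation-aligned epoching.

Fixation events travel as pandas DataFrames with the columns
``trial_id, subject_id, word_index, word_offset, onset_sample, duration_ms,
pass_index, condition`` (``word_offset`` is NaN for words outside -4..+3
around the target).  :func:`events_to_frame` converts the generator's
dataclass lists to this format; TSV round-trips go through
:func:`read_events_tsv` / :func:`write_events_tsv`.

Epoch windows use an explicit convention: 0-based samples, time 0 at the
alignment event, both window endpoints inclusive — a [-0.5, 0.5] s epoch at
1000 Hz has 1001 samples.  The fixation-duration filter keeps the closed
interval [0.08, 1] s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import FixationEvent, TrialRecording

__all__ = [
    "EpochSet",
    "EVENT_COLUMNS",
    "MIN_FIXATION_S",
    "MAX_FIXATION_S",
    "events_to_frame",
    "read_events_tsv",
    "write_events_tsv",
    "first_fixation_durations",
    "total_gaze_and_refixation",
    "extract_epochs",
    "extract_baseline_epochs",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "trial_id", "subject_id", "word_index", "word_offset",
    "onset_sample", "duration_ms", "pass_index", "condition",
]

MIN_FIXATION_S = 0.08
MAX_FIXATION_S = 1.0


@dataclass
class EpochSet:
    """Fixed-length event-aligned slices of sensor + photodiode data.

    ``sensor`` has shape (n_epochs, n_channels, n_samples); ``photodiode``
    (n_epochs, n_samples); ``meta`` one row per epoch with subject_id,
    trial_id, condition and duration_ms of the source fixation (NaN for
    baseline epochs).  ``n_excluded`` counts events dropped by the duration
    filter or by window bounds.
    """

    label: str
    window_s: tuple[float, float]
    sample_rate_hz: float
    sensor: np.ndarray
    photodiode: np.ndarray
    meta: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.sensor.shape[0] != self.photodiode.shape[0]:
            raise ValueError("sensor and photodiode epoch counts differ")
        if self.sensor.ndim != 3:
            raise ValueError("sensor must be (n_epochs, n_channels, n_samples)")
        if self.sensor.shape[-1] != self.photodiode.shape[-1]:
            raise ValueError("sensor and photodiode sample counts differ")

    def __len__(self) -> int:
        return self.sensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sensor.shape[1]

    @property
    def n_samples(self) -> int:
        return self.sensor.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds relative to the alignment event."""
        n = self.n_samples
        return self.window_s[0] + np.arange(n) / self.sample_rate_hz

    def subset(self, idx: Sequence[int] | np.ndarray, label: str | None = None) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            label=label or self.label,
            window_s=self.window_s,
            sample_rate_hz=self.sample_rate_hz,
            sensor=self.sensor[idx],
            photodiode=self.photodiode[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            n_excluded=self.n_excluded,
        )

    def by_condition(self, condition: str) -> "EpochSet":
        idx = np.flatnonzero(self.meta["condition"].to_numpy() == condition)
        return self.subset(idx, label=f"{self.label}:{condition}")


def events_to_frame(events: Iterable[FixationEvent]) -> pd.DataFrame:
    rows = [
        (e.trial_id, e.subject_id, e.word_index,
         np.nan if e.word_offset is None else e.word_offset,
         e.onset_sample, e.duration_ms, e.pass_index, e.condition)
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_tsv(events: pd.DataFrame | Iterable[FixationEvent], path) -> None:
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation TSV missing columns: {sorted(missing)}")
    return df


def _as_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    return events_to_frame(events)


def _first_pass_on_offset(events: pd.DataFrame, word_offset: int) -> pd.DataFrame:
    """Pass-1 fixations that first landed on the word at ``word_offset``."""
    if not -4 <= int(word_offset) <= 3:
        raise ValueError(f"word_offset must be in -4..+3, got {word_offset}")
    df = _as_frame(events)
    on_word = df[(df["word_offset"] == word_offset) & (df["pass_index"] == 1)]
    # "the fixation that first landed": earliest pass-1 fixation per trial
    first = (
        on_word.sort_values("onset_sample")
        .groupby(["subject_id", "trial_id"], as_index=False)
        .first()
    )
    return first


def first_fixation_durations(events, word_offset: int) -> pd.DataFrame:
    """First-fixation duration on a word, one row per trial that fixated it.

    Trials in which the word was skipped (no pass-1 fixation) are omitted.
    Columns: subject_id, trial_id, condition, duration_ms.
    """
    first = _first_pass_on_offset(events, word_offset)
    return first[["subject_id", "trial_id", "condition", "duration_ms"]].reset_index(
        drop=True
    )


def total_gaze_and_refixation(events, word_offset: int) -> pd.DataFrame:
    """Total gaze duration and refixation indicator per trial for a word.

    Total gaze sums every fixation on the word (all passes); the refixation
    indicator is True iff at least one fixation with pass_index > 1 exists.
    """
    if not -4 <= int(word_offset) <= 3:
        raise ValueError(f"word_offset must be in -4..+3, got {word_offset}")
    df = _as_frame(events)
    on_word = df[df["word_offset"] == word_offset]
    agg = on_word.groupby(["subject_id", "trial_id"]).agg(
        condition=("condition", "first"),
        total_gaze_ms=("duration_ms", "sum"),
        refixation=("pass_index", lambda p: bool((p > 1).any())),
    )
    return agg.reset_index()


def _window_samples(window_s: tuple[float, float], fs: float) -> tuple[int, int]:
    lo = int(round(window_s[0] * fs))
    hi = int(round(window_s[1] * fs))
    return lo, hi


def extract_epochs(
    recordings: TrialRecording | Iterable[TrialRecording],
    events,
    word_offset: int,
    window_s: tuple[float, float] = (-0.5, 0.5),
) -> EpochSet:
    """Fixation-aligned epochs for first-pass fixations on one word position.

    One epoch per retained fixation, aligned to fixation onset; fixations with
    duration outside [0.08, 1] s are excluded, as are fixations whose window
    would run past the recording (both counted in ``n_excluded``).  An empty
    result is a valid (empty) EpochSet.
    """
    if isinstance(recordings, TrialRecording):
        recordings = [recordings]
    recs = {(r.subject_id, r.trial_id): r for r in recordings}
    if not recs:
        raise ValueError("no recordings given")
    fs = {r.sample_rate_hz for r in recs.values()}
    if len(fs) != 1:
        raise ValueError("recordings have mixed sample rates")
    fs = fs.pop()
    lo, hi = _window_samples(window_s, fs)

    first = _first_pass_on_offset(events, word_offset)
    sensors, photos, rows = [], [], []
    n_excluded = 0
    for fx in first.itertuples(index=False):
        rec = recs.get((int(fx.subject_id), int(fx.trial_id)))
        if rec is None:
            continue
        dur_s = fx.duration_ms / 1000.0
        if not (MIN_FIXATION_S <= dur_s <= MAX_FIXATION_S):
            n_excluded += 1
            continue
        onset = int(fx.onset_sample)
        a, b = onset + lo, onset + hi
        if a < 0 or b >= rec.n_samples:
            n_excluded += 1
            continue
        sensors.append(rec.sensor_data[:, a : b + 1])
        photos.append(rec.photodiode[a : b + 1])
        rows.append(
            (rec.subject_id, rec.trial_id, fx.condition, fx.duration_ms)
        )
    if n_excluded:
        logger.info(
            "extract_epochs(offset=%d): excluded %d fixations", word_offset, n_excluded
        )
    n_samp = hi - lo + 1
    n_ch = next(iter(recs.values())).sensor_data.shape[0]
    meta = pd.DataFrame(
        rows, columns=["subject_id", "trial_id", "condition", "duration_ms"]
    )
    return EpochSet(
        label=f"offset{word_offset:+d}",
        window_s=window_s,
        sample_rate_hz=fs,
        sensor=(
            np.stack(sensors) if sensors else np.empty((0, n_ch, n_samp))
        ),
        photodiode=(
            np.stack(photos) if photos else np.empty((0, n_samp))
        ),
        meta=meta,
        n_excluded=n_excluded,
    )


def extract_baseline_epochs(
    recordings: TrialRecording | Iterable[TrialRecording],
    duration_s: float = 1.0,
) -> EpochSet:
    """One baseline epoch per trial: [0, 1] s from the cross-fixation onset.

    Trials whose window would exceed the recording are skipped and counted.
    """
    if isinstance(recordings, TrialRecording):
        recordings = [recordings]
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].sample_rate_hz
    n = int(round(duration_s * fs))
    sensors, photos, rows = [], [], []
    n_excluded = 0
    for rec in recordings:
        a = rec.cross_fixation_onset_sample
        b = a + n
        if b >= rec.n_samples:
            n_excluded += 1
            continue
        sensors.append(rec.sensor_data[:, a : b + 1])
        photos.append(rec.photodiode[a : b + 1])
        rows.append((rec.subject_id, rec.trial_id, rec.condition, np.nan))
    if n_excluded:
        logger.info("extract_baseline_epochs: skipped %d trials", n_excluded)
    n_ch = recordings[0].sensor_data.shape[0]
    meta = pd.DataFrame(
        rows, columns=["subject_id", "trial_id", "condition", "duration_ms"]
    )
    return EpochSet(
        label="baseline",
        window_s=(0.0, duration_s),
        sample_rate_hz=fs,
        sensor=np.stack(sensors) if sensors else np.empty((0, n_ch, n + 1)),
        photodiode=np.stack(photos) if photos else np.empty((0, n + 1)),
        meta=meta,
        n_excluded=n_excluded,
    )
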