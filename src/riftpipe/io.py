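"""Persistence: HDF5 trial containers, fixation TSVs, ground-truth sidecars.

Layout of the HDF5 container: one group per trial named
``subject<S>/trial<T>`` with datasets ``sensor_data`` (channels x samples)
and ``photodiode`` (samples), plus attributes ``sample_rate_hz``,
``condition``, ``cross_fixation_onset_sample`` and ``sentence_onset_sample``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synth import Dataset, GroundTruth, TrialRecording
from .events import events_to_frame, read_events_tsv, write_events_tsv

__all__ = [
    "write_recordings_h5",
    "read_recordings_h5",
    "write_truth_yaml",
    "read_truth_yaml",
    "save_dataset",
    "load_dataset",
]


def write_recordings_h5(recordings: dict[int, list[TrialRecording]], path) -> None:
    with h5py.File(path, "w") as f:
        for sid, recs in recordings.items():
            for rec in recs:
                g = f.create_group(f"subject{sid}/trial{rec.trial_id}")
                g.create_dataset("sensor_data", data=rec.sensor_data)
                g.create_dataset("photodiode", data=rec.photodiode)
                g.attrs["sample_rate_hz"] = rec.sample_rate_hz
                g.attrs["condition"] = rec.condition
                g.attrs["cross_fixation_onset_sample"] = rec.cross_fixation_onset_sample
                g.attrs["sentence_onset_sample"] = rec.sentence_onset_sample


def read_recordings_h5(path) -> dict[int, list[TrialRecording]]:
    out: dict[int, list[TrialRecording]] = {}
    with h5py.File(path, "r") as f:
        for sname, sgrp in f.items():
            sid = int(sname.removeprefix("subject"))
            recs = []
            for tname, g in sgrp.items():
                recs.append(
                    TrialRecording(
                        trial_id=int(tname.removeprefix("trial")),
                        subject_id=sid,
                        condition=str(g.attrs["condition"]),
                        sensor_data=np.asarray(g["sensor_data"]),
                        photodiode=np.asarray(g["photodiode"]),
                        sample_rate_hz=float(g.attrs["sample_rate_hz"]),
                        cross_fixation_onset_sample=int(
                            g.attrs["cross_fixation_onset_sample"]
                        ),
                        sentence_onset_sample=int(g.attrs["sentence_onset_sample"]),
                    )
                )
            out[sid] = sorted(recs, key=lambda r: r.trial_id)
    return out


def write_truth_yaml(truth: GroundTruth, path) -> None:
    d = dataclasses.asdict(truth)
    d["attention_envelope"] = {int(k): float(v)
                               for k, v in d["attention_envelope"].items()}
    for key in ("subject_speed_multipliers", "amplitude_factor_by_subject"):
        if d[key] is not None:
            d[key] = [float(v) for v in d[key]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_truth_yaml(path) -> GroundTruth:
    d = yaml.safe_load(Path(path).read_text())
    d["attention_envelope"] = {int(k): float(v)
                               for k, v in d["attention_envelope"].items()}
    return GroundTruth(**d)


def save_dataset(dataset: Dataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_recordings_h5(dataset.recordings, outdir / "recordings.h5")
    write_events_tsv(events_to_frame(dataset.events), outdir / "fixations.tsv")
    write_truth_yaml(dataset.truth, outdir / "ground_truth.yaml")


def load_dataset(outdir):
    """(recordings dict, events DataFrame, GroundTruth) from a saved dataset."""
    outdir = Path(outdir)
    recordings = read_recordings_h5(outdir / "recordings.h5")
    events = read_events_tsv(outdir / "fixations.tsv")
    truth = read_truth_yaml(outdir / "ground_truth.yaml")
    return recordings, events, truth
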