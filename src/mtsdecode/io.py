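"""CSV and HDF5 persistence for trials, sessions, epochs and results.

Formats:

* trial metadata — CSV, one row per trial attempt; times in ms, features as
  string enums, absent values empty.
* continuous session — HDF5 with ``/voltages`` (channels × samples,
  float32, µV), ``/events`` (label, sample_index, trial_id) and root
  attributes ``sampling_rate_hz``, ``channel_ids``.
* epochs — HDF5 group ``/epochs`` with the trials × channels × time tensor
  and the time axis, locking event and trial ids as attributes/datasets.
* decoding results — HDF5 with per-fold accuracies, the permutation-null
  ensemble and the significance trace, plus a tidy per-bin summary CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .decoding import DecoderSpec, DecodingTimecourse
from .inference import NullEnsemble, OnsetEstimate, SignificanceTrace
from .lfp import SessionRecording
from .preprocessing import EpochedData
from .task import TrialRecord

PathLike = Union[str, Path]

TRIAL_COLUMNS = [
    "trial_id", "session_id", "task_type", "sample_color", "sample_motion",
    "test_color", "test_motion", "is_target", "outcome", "reaction_time_ms",
    "delay_ms",
]


def write_trials_csv(records: Sequence[TrialRecord], path: PathLike) -> None:
    rows = [
        {
            "trial_id": r.trial_id,
            "session_id": r.session_id,
            "task_type": r.task_type,
            "sample_color": r.sample_color or "",
            "sample_motion": r.sample_motion or "",
            "test_color": r.test_color,
            "test_motion": r.test_motion,
            "is_target": int(r.is_target),
            "outcome": r.outcome,
            "reaction_time_ms": "" if r.reaction_time_ms is None else r.reaction_time_ms,
            "delay_ms": r.delay_ms,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path: PathLike) -> list[TrialRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        rt = row.reaction_time_ms
        records.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                session_id=str(row.session_id),
                task_type=row.task_type,
                sample_color=row.sample_color or None,
                sample_motion=row.sample_motion or None,
                test_color=row.test_color,
                test_motion=row.test_motion,
                is_target=bool(int(row.is_target)),
                outcome=row.outcome,
                reaction_time_ms=None if rt in ("", None) else float(rt),
                delay_ms=float(row.delay_ms),
            )
        )
    return records


def write_session_h5(recording: SessionRecording, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "voltages", data=recording.voltages.astype(np.float32), compression="gzip",
            compression_opts=1,
        )
        ev = f.create_group("events")
        ev.create_dataset(
            "label", data=np.asarray(recording.events["label"], dtype="S16")
        )
        ev.create_dataset("sample_index", data=recording.events["sample_index"].to_numpy())
        ev.create_dataset("trial_id", data=recording.events["trial_id"].to_numpy())
        f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        f.attrs["channel_ids"] = json.dumps(recording.channel_ids)


def read_session_h5(path: PathLike) -> SessionRecording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame(
            {
                "label": [s.decode() for s in f["events/label"][()]],
                "sample_index": f["events/sample_index"][()],
                "trial_id": f["events/trial_id"][()],
            }
        )
        return SessionRecording(
            voltages=f["voltages"][()],
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            events=events,
            channel_ids=json.loads(f.attrs["channel_ids"]),
        )


def write_epochs_h5(epochs: EpochedData, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data.astype(np.float32), compression="gzip",
                         compression_opts=1)
        g.create_dataset("time_ms", data=epochs.time_ms)
        g.create_dataset("trial_ids", data=epochs.trial_ids)
        g.attrs["lock_event"] = epochs.lock_event
        g.attrs["channel_ids"] = json.dumps(epochs.channel_ids)


def read_epochs_h5(path: PathLike) -> EpochedData:
    with h5py.File(path, "r") as f:
        g = f["epochs"]
        return EpochedData(
            data=g["data"][()],
            time_ms=g["time_ms"][()],
            lock_event=g.attrs["lock_event"],
            trial_ids=g["trial_ids"][()],
            channel_ids=json.loads(g.attrs["channel_ids"]),
        )


def write_decoding_h5(
    path: PathLike,
    timecourse: DecodingTimecourse,
    null: Optional[NullEnsemble] = None,
    trace: Optional[SignificanceTrace] = None,
    onset: Optional[OnsetEstimate] = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracies", data=timecourse.accuracies)
        f.create_dataset("time_ms", data=timecourse.time_ms)
        f.attrs["n_classes"] = timecourse.n_classes
        f.attrs["class_names"] = json.dumps([str(c) for c in timecourse.class_names])
        f.attrs["seed"] = timecourse.seed
        f.attrs["name"] = timecourse.name
        f.attrs["spec"] = json.dumps(vars(timecourse.spec))
        if null is not None:
            g = f.create_group("null")
            g.create_dataset("accuracies", data=null.accuracies)
            g.create_dataset("seeds", data=null.seeds)
        if trace is not None:
            g = f.create_group("significance")
            g.create_dataset("z", data=trace.z)
            g.create_dataset("p", data=trace.p)
            g.create_dataset("significant", data=trace.significant)
            g.attrs["alpha"] = trace.alpha
        if onset is not None:
            f.attrs["onset_ms"] = np.nan if onset.onset_ms is None else onset.onset_ms
            f.attrs["onset_window_ms"] = onset.window_ms


def read_decoding_h5(path: PathLike):
    """Returns (timecourse, null or None, trace or None, onset or None)."""
    with h5py.File(path, "r") as f:
        spec = DecoderSpec(**json.loads(f.attrs["spec"]))
        tc = DecodingTimecourse(
            time_ms=f["time_ms"][()],
            accuracies=f["accuracies"][()],
            n_classes=int(f.attrs["n_classes"]),
            class_names=np.asarray(json.loads(f.attrs["class_names"])),
            seed=int(f.attrs["seed"]),
            spec=spec,
            name=str(f.attrs["name"]),
        )
        null = trace = onset = None
        if "null" in f:
            null = NullEnsemble(
                accuracies=f["null/accuracies"][()],
                time_ms=tc.time_ms.copy(),
                seeds=f["null/seeds"][()],
                name=f"{tc.name}:null",
            )
        if "significance" in f:
            g = f["significance"]
            trace = SignificanceTrace(
                time_ms=tc.time_ms.copy(),
                z=g["z"][()],
                p=g["p"][()],
                significant=g["significant"][()].astype(bool),
                alpha=float(g.attrs["alpha"]),
            )
        if "onset_ms" in f.attrs:
            v = float(f.attrs["onset_ms"])
            onset = OnsetEstimate(
                None if np.isnan(v) else v, float(f.attrs["onset_window_ms"])
            )
        return tc, null, trace, onset


def timecourse_summary(
    timecourse: DecodingTimecourse,
    trace: Optional[SignificanceTrace] = None,
) -> pd.DataFrame:
    """Tidy per-bin summary (time, mean accuracy, fold SD, z, p, flag)."""
    out = pd.DataFrame(
        {
            "time_ms": timecourse.time_ms,
            "mean_accuracy": timecourse.mean,
            "fold_sd": timecourse.accuracies.std(axis=0, ddof=1),
        }
    )
    if trace is not None:
        out["z"] = trace.z
        out["p"] = trace.p
        out["significant"] = trace.significant.astype(int)
    return out
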