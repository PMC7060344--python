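"""Config-driven end-to-end analysis runs.

A run executes: simulate (or load) → preprocess → epoch → select & balance
→ decode → permutation null → significance → onset, and persists each
stage's output under the run directory.  Three analysis designs are
supported, each realizing the balancing statement appropriate for its
question:

* ``feature_decoding`` — labels are the test color (or motion) of correct
  trials of one task; the other test feature and the outcome are balancing
  covariates.  Chance 1/4.
* ``outcome_decoding`` — labels are hit vs correct rejection; both test
  features are covariates and hits faster than 300 ms are excluded, so
  decodable signal precedes any admissible button press.  Chance 1/2.
* ``match_decoding`` — conjunction-task correct rejections only: test
  stimuli matching exactly one searched-for feature against complete
  mismatches.  All trials share the same (non-)motor outcome, isolating
  match relevance from motor preparation.  Chance 1/2.

Every random draw derives from one master seed via named substreams, so a
run is reproducible end to end from its config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .decoding import DecoderSpec, LabeledDataset
from .inference import (
    ALPHA_DECODING,
    ONSET_WINDOW_MS,
    OnsetEstimate,
    detect_onset,
    permutation_null,
    run_balanced_decoding,
    significance_trace,
)
from .lfp import EffectComponent, SessionRecording, SignalSpec, synthesize_lfp
from .observer import BehaviorParams, simulate_behavior
from .preprocessing import EpochedData, PreprocParams, epoch, preprocess_continuous
from .task import CONJUNCTION_TASK, TASK_TYPES, TaskConfig, TrialRecord, build_trial_pool

RT_FLOOR_MS = 300.0

ANALYSES = ("feature_decoding", "outcome_decoding", "match_decoding")


class ConfigError(ValueError):
    """Raised with a field-level message for invalid configurations."""


@dataclass
class SimulateConfig:
    n_repeats: int = 1
    tasks: Sequence[str] = TASK_TYPES
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    signal: SignalSpec = field(default_factory=SignalSpec)
    task_config: TaskConfig = field(default_factory=TaskConfig)
    abort_rate: float = 0.0
    session_id: str = "synthetic"


@dataclass
class AnalysisConfig:
    """Validated configuration of one end-to-end run."""

    analysis: str = "feature_decoding"
    label: str = "test_color"          # feature_decoding: which feature
    tasks: Sequence[str] = ("color",)  # analyzed separately per task
    match_subtype: str = "color"       # match_decoding: color or motion half-match
    lock_event: str = "test_on"
    window_ms: tuple[float, float] = (-100.0, 300.0)
    simulate: Optional[SimulateConfig] = field(default_factory=SimulateConfig)
    trials_csv: Optional[str] = None   # used when simulate is None
    session_h5: Optional[str] = None
    preproc: PreprocParams = field(default_factory=PreprocParams)
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    n_perm: int = 100
    alpha: float = ALPHA_DECODING
    onset_window_ms: float = ONSET_WINDOW_MS
    exclude_channels: Sequence[int] = ()
    save_session: bool = False

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigError(
                f"analysis: {self.analysis!r} not one of {ANALYSES}"
            )
        if self.label not in ("test_color", "test_motion"):
            raise ConfigError(f"label: {self.label!r} must be test_color or test_motion")
        if self.match_subtype not in ("color", "motion"):
            raise ConfigError(f"match_subtype: {self.match_subtype!r}")
        bad = set(self.tasks) - set(TASK_TYPES)
        if bad:
            raise ConfigError(f"tasks: unknown task types {sorted(bad)}")
        if self.lock_event not in ("sample_on", "test_on"):
            raise ConfigError(f"lock_event: {self.lock_event!r}")
        if self.n_perm < 2:
            raise ConfigError(f"n_perm: {self.n_perm} must be >= 2")
        if self.simulate is None and (self.trials_csv is None or self.session_h5 is None):
            raise ConfigError(
                "either simulate must be configured or both trials_csv and "
                "session_h5 must be given"
            )


def _build_nested(cls, data: dict, path: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    bad = set(data) - set(known)
    if bad:
        raise ConfigError(f"{path}: unknown field(s) {sorted(bad)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(data: dict) -> AnalysisConfig:
    """Build and validate a config from a plain (YAML-loaded) mapping."""
    data = dict(data)
    if "simulate" in data and data["simulate"] is not None:
        sim = dict(data["simulate"])
        if "behavior" in sim:
            sim["behavior"] = _build_nested(BehaviorParams, sim["behavior"], "simulate.behavior")
        if "signal" in sim:
            sig = dict(sim["signal"])
            effects = tuple(
                _build_nested(EffectComponent, dict(e), f"simulate.signal.effects[{i}]")
                for i, e in enumerate(sig.pop("effects", []))
            )
            sim["signal"] = _build_nested(
                SignalSpec, {**sig, "effects": effects}, "simulate.signal"
            )
        if "task_config" in sim:
            sim["task_config"] = _build_nested(TaskConfig, sim["task_config"], "simulate.task_config")
        data["simulate"] = _build_nested(SimulateConfig, sim, "simulate")
    for key, cls in (("preproc", PreprocParams), ("decoder", DecoderSpec)):
        if key in data and isinstance(data[key], dict):
            data[key] = _build_nested(cls, data[key], key)
    if "window_ms" in data:
        data["window_ms"] = tuple(data["window_ms"])
    return _build_nested(AnalysisConfig, data, "config")


def config_from_yaml(path) -> AnalysisConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f) or {})


def derive_seeds(master_seed: int, names: Sequence[str]) -> dict[str, int]:
    """Named, independent substream seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


# ---------------------------------------------------------------- datasets

def _records_by_id(records: Sequence[TrialRecord]) -> dict[int, TrialRecord]:
    return {r.trial_id: r for r in records}


def _dataset_from(
    epochs: EpochedData,
    records: Sequence[TrialRecord],
    keep,
    label_of,
    covariates_of,
    name: str,
) -> LabeledDataset:
    by_id = _records_by_id(records)
    mask, labels, covs = [], [], []
    for tid in epochs.trial_ids:
        rec = by_id[int(tid)]
        ok = keep(rec)
        mask.append(ok)
        if ok:
            labels.append(label_of(rec))
            covs.append(covariates_of(rec))
    if not any(mask):
        raise ConfigError(f"{name}: selection rule retained no trials")
    return LabeledDataset(
        epochs=epochs.select(np.asarray(mask, dtype=bool)),
        labels=np.asarray(labels),
        covariates=np.asarray(covs, dtype=object),
        name=name,
    )


def build_feature_dataset(
    epochs: EpochedData,
    records: Sequence[TrialRecord],
    feature: str = "test_color",
    task: str = "color",
) -> LabeledDataset:
    """Stimulus-feature decoding on correct trials of one task."""
    other = "test_motion" if feature == "test_color" else "test_color"
    return _dataset_from(
        epochs, records,
        keep=lambda r: r.task_type == task and r.correct,
        label_of=lambda r: getattr(r, feature),
        covariates_of=lambda r: (getattr(r, other), r.outcome),
        name=f"{feature}:{task}",
    )


def build_outcome_dataset(
    epochs: EpochedData,
    records: Sequence[TrialRecord],
    task: str,
    rt_floor_ms: float = RT_FLOOR_MS,
    covariates: Sequence[str] = ("test_color", "test_motion"),
) -> LabeledDataset:
    """Hit vs correct-rejection prediction; fast hits excluded."""

    def keep(r: TrialRecord) -> bool:
        if r.task_type != task or not r.correct:
            return False
        if r.reaction_time_ms is not None and r.reaction_time_ms < rt_floor_ms:
            return False
        return True

    return _dataset_from(
        epochs, records,
        keep=keep,
        label_of=lambda r: r.outcome,
        covariates_of=lambda r: tuple(getattr(r, c) for c in covariates),
        name=f"outcome:{task}",
    )


def build_match_dataset(
    epochs: EpochedData,
    records: Sequence[TrialRecord],
    subtype: str = "color",
    covariates: Sequence[str] = ("test_color", "test_motion"),
) -> LabeledDataset:
    """Half-match vs complete-mismatch among conjunction correct rejections.

    ``subtype="color"`` contrasts test stimuli matching the searched-for
    color only (motion mismatches) with complete mismatches; all trials are
    correct rejections, so the motor outcome is constant.
    """
    half = "motion_mismatch" if subtype == "color" else "color_mismatch"

    def keep(r: TrialRecord) -> bool:
        return (
            r.task_type == CONJUNCTION_TASK
            and r.outcome == "correct_rejection"
            and r.mismatch_type in (half, "complete_mismatch")
        )

    return _dataset_from(
        epochs, records,
        keep=keep,
        label_of=lambda r: "half_match" if r.mismatch_type == half else "complete_mismatch",
        covariates_of=lambda r: tuple(getattr(r, c) for c in covariates),
        name=f"match:{subtype}",
    )


# ---------------------------------------------------------------- pipeline

def simulate_session(
    sim: SimulateConfig, seed: int
) -> tuple[list[TrialRecord], SessionRecording, object]:
    """Generate trial records and the continuous recording for one session."""
    seeds = derive_seeds(seed, ["behavior", "lfp"])
    pool = [
        t
        for t in build_trial_pool(sim.task_config, sim.n_repeats)
        if t.task_type in sim.tasks
    ]
    records = simulate_behavior(
        pool, sim.behavior, seeds["behavior"],
        task_config=sim.task_config, session_id=sim.session_id,
        abort_rate=sim.abort_rate,
    )
    recording, truth = synthesize_lfp(
        records, sim.signal, seeds["lfp"],
        sample_dur_ms=sim.task_config.sample_dur_ms,
        test_dur_ms=sim.task_config.test_dur_ms,
        response_window_ms=sim.task_config.response_window_ms,
    )
    return records, recording, truth


def _analysis_datasets(config: AnalysisConfig, epochs, records):
    out = []
    if config.analysis == "feature_decoding":
        for task in config.tasks:
            out.append(build_feature_dataset(epochs, records, config.label, task))
    elif config.analysis == "outcome_decoding":
        for task in config.tasks:
            out.append(build_outcome_dataset(epochs, records, task))
    else:
        out.append(build_match_dataset(epochs, records, config.match_subtype))
    return out


def run_pipeline(config: AnalysisConfig, seed: int, out_dir) -> dict:
    """Execute one full analysis run and persist per-stage outputs.

    Returns ``{dataset name: {"timecourse", "null", "trace", "onset"}}``;
    writes trials.csv, epochs.h5, one decoding HDF5 per analyzed dataset and
    a summary.csv into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(seed, ["session", "observed", "null"])

    if config.simulate is not None:
        records, recording, _ = simulate_session(config.simulate, seeds["session"])
    else:
        records = mio.read_trials_csv(config.trials_csv)
        recording = mio.read_session_h5(config.session_h5)
    mio.write_trials_csv(records, out / "trials.csv")
    if config.save_session:
        mio.write_session_h5(recording, out / "session.h5")

    pre = preprocess_continuous(recording, config.preproc)
    if config.exclude_channels:
        keep = [c for c in range(pre.n_channels) if c not in set(config.exclude_channels)]
        pre = SessionRecording(
            voltages=pre.voltages[keep],
            sampling_rate_hz=pre.sampling_rate_hz,
            events=pre.events,
            channel_ids=[pre.channel_ids[c] for c in keep],
        )
    epochs = epoch(
        pre, records, config.lock_event, config.window_ms,
        outcomes=("hit", "correct_rejection"),
        reject_clipping=True, clip_params=config.preproc,
    )
    mio.write_epochs_h5(epochs, out / "epochs.h5")

    results: dict[str, dict] = {}
    rows = []
    for i, dataset in enumerate(_analysis_datasets(config, epochs, records)):
        obs_seed = seeds["observed"] + i
        null_seed = seeds["null"] + i
        tc = run_balanced_decoding(dataset, config.decoder, obs_seed)
        null = permutation_null(dataset, config.decoder, config.n_perm, null_seed)
        trace = significance_trace(tc, null, config.alpha)
        onset = detect_onset(trace, config.onset_window_ms)
        key = dataset.name.replace(":", "_")
        mio.write_decoding_h5(out / f"{key}.h5", tc, null, trace, onset)
        mio.timecourse_summary(tc, trace).to_csv(out / f"{key}_bins.csv", index=False)
        results[dataset.name] = {
            "timecourse": tc, "null": null, "trace": trace, "onset": onset,
            "dataset": dataset,
        }
        rows.append(
            {
                "analysis": config.analysis,
                "dataset": dataset.name,
                "n_trials": len(dataset.labels),
                "n_classes": dataset.n_classes,
                "chance": round(dataset.chance_level, 6),
                "onset_ms": "" if onset.onset_ms is None else onset.onset_ms,
                "n_significant_bins": int(trace.significant.sum()),
                "peak_accuracy": round(float(tc.mean.max()), 6),
                "n_perm": config.n_perm,
                "alpha": config.alpha,
                "seed": seed,
            }
        )
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    with open(out / "provenance.json", "w") as f:
        json.dump(
            {
                "master_seed": seed,
                "stage_seeds": seeds,
                "analysis": config.analysis,
                "n_perm": config.n_perm,
                "alpha": config.alpha,
                "excluded_channels": list(config.exclude_channels),
            },
            f, indent=2, sort_keys=True,
        )
    return results
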