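"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mtsdecode.lfp import EffectComponent, SignalSpec, synthesize_lfp
from mtsdecode.observer import BehaviorParams, simulate_behavior
from mtsdecode.preprocessing import EpochedData, epoch, preprocess_continuous
from mtsdecode.task import TaskConfig, build_trial_pool


def make_noise_epochs(
    n_trials: int, n_channels: int, n_bins: int, seed: int = 0
) -> EpochedData:
    """Pure-noise epochs on the standard 4 ms grid."""
    rng = np.random.default_rng(seed)
    return EpochedData(
        data=rng.normal(size=(n_trials, n_channels, n_bins)).astype(np.float32),
        time_ms=np.arange(n_bins) * 4.0,
        lock_event="test_on",
        trial_ids=np.arange(n_trials),
        channel_ids=[f"ch{c:03d}" for c in range(n_channels)],
    )


@pytest.fixture(scope="session")
def color_session():
    """A color-task session with a strong color-identity effect at 120 ms.

    Returns (records, recording, ground_truth, preprocessed, epochs); built
    once and shared — treat as read-only.
    """
    cfg = TaskConfig()
    pool = [t for t in build_trial_pool(cfg, 5) if t.task_type == "color"]
    params = BehaviorParams(dprime_color=2.5, dprime_motion=2.5)
    records = simulate_behavior(pool, params, seed=101, task_config=cfg)
    spec = SignalSpec(
        n_channels=8,
        effects=(
            EffectComponent(
                "color_identity", latency_ms=120.0, duration_ms=220.0, amplitude=5.0
            ),
        ),
    )
    recording, truth = synthesize_lfp(records, spec, seed=202)
    pre = preprocess_continuous(recording)
    epochs = epoch(
        pre, records, "test_on", (-100.0, 300.0),
        outcomes=("hit", "correct_rejection"),
    )
    return records, recording, truth, pre, epochs
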