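"""Generative signal-detection observer for the match-to-sample task.

The observer is an equal-variance Gaussian model.  On every trial it draws
one evidence value per task-relevant feature: ``N(d', 1)`` when the test
matches that feature of the sample, ``N(0, 1)`` otherwise.  Single-feature
rules threshold that evidence directly; the conjunction rule takes the
*minimum* of the two feature evidences, since both features must match for a
target.  This reproduces the qualitative behavioral signature of conjunction
matching: sensitivity against single-feature mismatches is lower than
against complete mismatches.

Reaction times for button presses follow a shifted log-normal; presses
falling beyond the response window count as no-response.  Incorrectly
answered (and optionally aborted) trials re-enter the pending pool at a
uniformly random later position and are re-tested, while the failed attempt
is retained in the output — matching a session protocol where errors are
re-queued to counteract stimulus- or response-specific biases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task import CONJUNCTION_TASK, TaskConfig, TrialRecord, TrialSpec


class BehaviorParamsError(ValueError):
    """Raised for invalid observer parameters."""


@dataclass(frozen=True)
class BehaviorParams:
    """Observer parameters.

    ``dprime_color`` / ``dprime_motion`` are the per-feature sensitivities on
    the d' scale (mean evidence shift for a matching feature).  ``criterion``
    is the absolute decision threshold on the evidence axis; ``None`` places
    it halfway between the non-match and match evidence means (the unbiased
    choice), i.e. at d'/2 of the relevant feature and at min(d'c, d'm)/2 for
    the conjunction rule.  The reaction-time model is
    ``shift + LogNormal(mu, sigma)`` in milliseconds; with the defaults the
    median press lands near 370 ms and a small natural fraction falls below
    300 ms, exercising downstream reaction-time exclusion rules.
    """

    dprime_color: float = 1.5
    dprime_motion: float = 1.5
    criterion: float | None = None
    rt_shift_ms: float = 250.0
    rt_mu: float = math.log(120.0)
    rt_sigma: float = 0.5
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.dprime_color < 0 or self.dprime_motion < 0:
            raise BehaviorParamsError("sensitivities must be nonnegative")
        if self.rt_shift_ms < 0:
            raise BehaviorParamsError("rt_shift_ms must be >= 0")
        if not 0 <= self.lapse_rate < 1:
            raise BehaviorParamsError("lapse_rate must be in [0, 1)")
        if self.rt_sigma <= 0:
            raise BehaviorParamsError("rt_sigma must be > 0")

    def threshold(self, task_type: str) -> float:
        if self.criterion is not None:
            return self.criterion
        if task_type == "color":
            return self.dprime_color / 2.0
        if task_type == "motion":
            return self.dprime_motion / 2.0
        return min(self.dprime_color, self.dprime_motion) / 2.0


def _decides_match(
    spec: TrialSpec, params: BehaviorParams, rng: np.random.Generator
) -> bool:
    evidences = []
    if spec.sample_color is not None:
        mu = params.dprime_color if spec.test_color == spec.sample_color else 0.0
        evidences.append(rng.normal(mu, 1.0))
    if spec.sample_motion is not None:
        mu = params.dprime_motion if spec.test_motion == spec.sample_motion else 0.0
        evidences.append(rng.normal(mu, 1.0))
    return min(evidences) > params.threshold(spec.task_type)


def simulate_behavior(
    pool: list[TrialSpec],
    params: BehaviorParams,
    seed: int,
    *,
    task_config: TaskConfig | None = None,
    session_id: str = "synthetic",
    abort_rate: float = 0.0,
    reenter_aborted: bool = True,
    max_trials: int | None = None,
) -> list[TrialRecord]:
    """Run the observer over the pool until every entry is answered correctly.

    Trials are drawn without replacement from a shuffled copy of ``pool``.
    An incorrect attempt (miss or false alarm) re-queues the entry at a
    uniformly random later position; whether fixation-break aborts re-enter
    as well is controlled by ``reenter_aborted``.  Every attempt — including
    errors and aborts — appears in the returned records in presentation
    order.  ``max_trials`` optionally caps the number of attempts.
    """
    if not pool:
        raise ValueError("trial pool is empty")
    if not 0 <= abort_rate < 1:
        raise ValueError("abort_rate must be in [0, 1)")
    cfg = task_config or TaskConfig()
    rng = np.random.default_rng(seed)

    pending: list[TrialSpec] = list(pool)
    rng.shuffle(pending)  # type: ignore[arg-type]
    records: list[TrialRecord] = []
    lo, hi = cfg.delay_range_ms

    while pending:
        if max_trials is not None and len(records) >= max_trials:
            break
        spec = pending.pop(0)
        delay = float(rng.uniform(lo, hi))
        trial_id = len(records)

        if abort_rate > 0 and rng.random() < abort_rate:
            records.append(
                TrialRecord(
                    trial_id, session_id, spec.task_type, spec.sample_color,
                    spec.sample_motion, spec.test_color, spec.test_motion,
                    spec.is_target, "aborted", None, delay,
                )
            )
            if reenter_aborted:
                _requeue(pending, spec, rng)
            continue

        if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
            says_match = bool(rng.random() < 0.5)
        else:
            says_match = _decides_match(spec, params, rng)

        rt: float | None = None
        if says_match:
            rt = params.rt_shift_ms + float(rng.lognormal(params.rt_mu, params.rt_sigma))
            if rt > cfg.response_window_ms:  # press after window: no response
                rt = None
                says_match = False

        if spec.is_target:
            outcome = "hit" if says_match else "miss"
        else:
            outcome = "false_alarm" if says_match else "correct_rejection"
        records.append(
            TrialRecord(
                trial_id, session_id, spec.task_type, spec.sample_color,
                spec.sample_motion, spec.test_color, spec.test_motion,
                spec.is_target, outcome, rt, delay,
            )
        )
        if outcome in ("miss", "false_alarm"):
            _requeue(pending, spec, rng)
    return records


def _requeue(pending: list[TrialSpec], spec: TrialSpec, rng: np.random.Generator) -> None:
    pos = int(rng.integers(0, len(pending) + 1))
    pending.insert(pos, spec)
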