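"""Delayed match-to-sample task structure and trial-pool construction.

A session interleaves three task rules. The sample stimulus both cues the
rule and carries the feature(s) to remember:

* ``color`` task   — sample is colored but moves incoherently; only the test
  color must be matched.
* ``motion`` task  — sample is grey but moves coherently; only the test
  motion direction must be matched.
* ``conjunction``  — sample carries both features; the test is a target only
  if *both* match.

Features are grouped into two opposed pairs so that a non-matching test
always shows the pair partner of the remembered feature.  Within every task
rule the trial pool makes each test configuration equally likely among
non-targets and fixes the target probability at exactly 1/2; for the
conjunction rule this requires the full-match configuration to appear as
often as the three mismatch configurations combined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

COLOR_TASK = "color"
MOTION_TASK = "motion"
CONJUNCTION_TASK = "conjunction"
TASK_TYPES = (COLOR_TASK, MOTION_TASK, CONJUNCTION_TASK)

OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection", "aborted")

DEFAULT_COLORS = ("orange", "cyan", "green", "magenta")
DEFAULT_MOTIONS = ("up", "down", "left", "right")


class TaskConfigError(ValueError):
    """Raised for inconsistent task configurations."""


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus set, epoch durations and rule set of the task.

    ``color_pairs`` / ``motion_pairs`` partition the four feature values into
    two opposed pairs; a mismatching test always shows the pair partner.
    Durations are in milliseconds; the delay is drawn uniformly from
    ``delay_range_ms``.
    """

    colors: Sequence[str] = DEFAULT_COLORS
    motions: Sequence[str] = DEFAULT_MOTIONS
    color_pairs: Sequence[Sequence[str]] = (("orange", "cyan"), ("green", "magenta"))
    motion_pairs: Sequence[Sequence[str]] = (("up", "down"), ("left", "right"))
    sample_dur_ms: float = 1000.0
    delay_range_ms: tuple[float, float] = (800.0, 1600.0)
    test_dur_ms: float = 250.0
    response_window_ms: float = 600.0
    task_types: Sequence[str] = TASK_TYPES

    def __post_init__(self) -> None:
        for pairs, feats, name in (
            (self.color_pairs, self.colors, "color"),
            (self.motion_pairs, self.motions, "motion"),
        ):
            flat = [f for pair in pairs for f in pair]
            if sorted(flat) != sorted(feats):
                raise TaskConfigError(
                    f"{name}_pairs {pairs!r} do not partition {tuple(feats)!r}"
                )
            if any(len(pair) != 2 for pair in pairs):
                raise TaskConfigError(f"{name}_pairs must contain pairs")
        unknown = set(self.task_types) - set(TASK_TYPES)
        if unknown:
            raise TaskConfigError(f"unknown task types: {sorted(unknown)}")
        lo, hi = self.delay_range_ms
        if not (0 <= lo <= hi):
            raise TaskConfigError(f"invalid delay range {self.delay_range_ms}")

    def opposite_color(self, color: str) -> str:
        return _pair_partner(self.color_pairs, color)

    def opposite_motion(self, motion: str) -> str:
        return _pair_partner(self.motion_pairs, motion)


def _pair_partner(pairs: Sequence[Sequence[str]], value: str) -> str:
    for a, b in pairs:
        if value == a:
            return b
        if value == b:
            return a
    raise KeyError(value)


@dataclass(frozen=True)
class TrialSpec:
    """One pool entry: a task rule plus sample and test feature assignment.

    ``sample_color is None`` encodes a grey sample (motion task);
    ``sample_motion is None`` encodes incoherent motion (color task).
    """

    task_type: str
    sample_color: Optional[str]
    sample_motion: Optional[str]
    test_color: str
    test_motion: str

    @property
    def is_target(self) -> bool:
        return is_target(
            self.task_type,
            self.sample_color,
            self.sample_motion,
            self.test_color,
            self.test_motion,
        )

    @property
    def color_match(self) -> Optional[bool]:
        """Whether the test matches the searched-for color (None if color is
        irrelevant for this rule)."""
        if self.sample_color is None:
            return None
        return self.test_color == self.sample_color

    @property
    def motion_match(self) -> Optional[bool]:
        if self.sample_motion is None:
            return None
        return self.test_motion == self.sample_motion

    @property
    def mismatch_type(self) -> Optional[str]:
        """For conjunction non-targets: which feature(s) fail to match.

        One of ``color_mismatch`` (color differs, motion matches),
        ``motion_mismatch``, ``complete_mismatch``; ``None`` for targets or
        single-feature rules.
        """
        if self.task_type != CONJUNCTION_TASK or self.is_target:
            return None
        cm, mm = self.color_match, self.motion_match
        if not cm and mm:
            return "color_mismatch"
        if cm and not mm:
            return "motion_mismatch"
        return "complete_mismatch"


def is_target(
    task_type: str,
    sample_color: Optional[str],
    sample_motion: Optional[str],
    test_color: str,
    test_motion: str,
) -> bool:
    """Target status is a pure function of rule and feature equality."""
    if task_type == COLOR_TASK:
        return test_color == sample_color
    if task_type == MOTION_TASK:
        return test_motion == sample_motion
    if task_type == CONJUNCTION_TASK:
        return test_color == sample_color and test_motion == sample_motion
    raise ValueError(f"unknown task type {task_type!r}")


@dataclass
class TrialRecord:
    """One realized trial attempt with its behavioral outcome."""

    trial_id: int
    session_id: str
    task_type: str
    sample_color: Optional[str]
    sample_motion: Optional[str]
    test_color: str
    test_motion: str
    is_target: bool
    outcome: str
    reaction_time_ms: Optional[float]
    delay_ms: float

    @property
    def spec(self) -> TrialSpec:
        return TrialSpec(
            self.task_type,
            self.sample_color,
            self.sample_motion,
            self.test_color,
            self.test_motion,
        )

    @property
    def correct(self) -> bool:
        return self.outcome in ("hit", "correct_rejection")

    @property
    def responded(self) -> bool:
        return self.outcome in ("hit", "false_alarm")

    @property
    def mismatch_type(self) -> Optional[str]:
        return self.spec.mismatch_type


def build_trial_pool(config: TaskConfig, n_repeats: int) -> list[TrialSpec]:
    """Enumerate the balanced trial pool, ``n_repeats`` copies per entry.

    Per repeat and rule the pool contains every sample assignment crossed
    with every admissible test: for single-feature rules the relevant test
    feature is same-or-opposite crossed with all four values of the
    irrelevant feature (32 entries, half targets); for the conjunction rule
    each sample meets its full match three times plus each of the three
    mismatch configurations once (96 entries, half targets).
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    pool: list[TrialSpec] = []
    for task in config.task_types:
        pool.extend(_rule_pool(config, task))
    return [replace(t) for t in pool for _ in range(n_repeats)]


def _rule_pool(config: TaskConfig, task: str) -> list[TrialSpec]:
    entries: list[TrialSpec] = []
    if task == COLOR_TASK:
        for sc, tm in itertools.product(config.colors, config.motions):
            for tc in (sc, config.opposite_color(sc)):
                entries.append(TrialSpec(task, sc, None, tc, tm))
    elif task == MOTION_TASK:
        for sm, tc in itertools.product(config.motions, config.colors):
            for tm in (sm, config.opposite_motion(sm)):
                entries.append(TrialSpec(task, None, sm, tc, tm))
    elif task == CONJUNCTION_TASK:
        for sc, sm in itertools.product(config.colors, config.motions):
            oc, om = config.opposite_color(sc), config.opposite_motion(sm)
            entries.extend([TrialSpec(task, sc, sm, sc, sm)] * 3)
            entries.append(TrialSpec(task, sc, sm, oc, sm))
            entries.append(TrialSpec(task, sc, sm, sc, om))
            entries.append(TrialSpec(task, sc, sm, oc, om))
    else:
        raise ValueError(f"unknown task type {task!r}")
    return entries
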