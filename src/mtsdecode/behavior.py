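"""Signal-detection behavioral statistics: d' by contrast and RT tests.

Sensitivity is d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate) with the
log-linear correction (0.5 added to each cell, 1 to each denominator)
applied unconditionally, which keeps d' finite at perfect rates and removes
the discontinuity a conditional correction would introduce.

For the conjunction rule, mismatch trials are grouped into three types —
color-mismatch (color differs, motion matches), motion-mismatch, and
complete-mismatch — and each is contrasted against the full-match trials,
yielding three d' values per session.  A contrast against color-mismatch
trials isolates the *color-relevant* sensitivity (only color distinguishes
target from non-target), and analogously for motion.  Session-wise values
feed paired t-tests at a Bonferroni-corrected alpha of 0.005.

Reaction-time comparisons transform latencies to speed (1000 / RT, in 1/s)
before a two-sample t-test; untransformed and rank-based variants are
reported as robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONJUNCTION_TASK, TrialRecord

BONFERRONI_ALPHA = 0.005

#: contrast name -> (task, mismatch type defining the noise trials)
CONTRASTS = {
    "conjunction_color": (CONJUNCTION_TASK, "color_mismatch"),
    "conjunction_motion": (CONJUNCTION_TASK, "motion_mismatch"),
    "conjunction_complete": (CONJUNCTION_TASK, "complete_mismatch"),
    "color_task": ("color", None),
    "motion_task": ("motion", None),
}


@dataclass(frozen=True)
class OutcomeCounts:
    n_hit: int
    n_miss: int
    n_fa: int
    n_cr: int

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_miss, self.n_fa, self.n_cr) < 0:
            raise ValueError("counts must be nonnegative")


def dprime(counts: OutcomeCounts) -> float:
    """Log-linear-corrected sensitivity index.

    Raises when either the signal (hit+miss) or noise (fa+cr) side has no
    trials, since the corresponding rate is undefined.
    """
    n_signal = counts.n_hit + counts.n_miss
    n_noise = counts.n_fa + counts.n_cr
    if n_signal < 1 or n_noise < 1:
        raise ValueError("d' undefined: need at least one signal and one noise trial")
    hr = (counts.n_hit + 0.5) / (n_signal + 1)
    far = (counts.n_fa + 0.5) / (n_noise + 1)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def _counts(signal: Iterable[TrialRecord], noise: Iterable[TrialRecord]) -> OutcomeCounts:
    s = list(signal)
    n = list(noise)
    return OutcomeCounts(
        n_hit=sum(r.outcome == "hit" for r in s),
        n_miss=sum(r.outcome == "miss" for r in s),
        n_fa=sum(r.outcome == "false_alarm" for r in n),
        n_cr=sum(r.outcome == "correct_rejection" for r in n),
    )


def dprime_by_contrast(trial_records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-session d' for every behavioral contrast.

    Returns a tidy frame (session, contrast, dprime, n_signal, n_noise).
    The "match" reference for the three conjunction contrasts is the set of
    full-feature targets (hits and misses); a session lacking trials for a
    contrast contributes no row for it.
    """
    rows = []
    recs = [r for r in trial_records if r.outcome != "aborted"]
    sessions = sorted({r.session_id for r in recs})
    for sess in sessions:
        in_sess = [r for r in recs if r.session_id == sess]
        for name, (task, mismatch) in CONTRASTS.items():
            of_task = [r for r in in_sess if r.task_type == task]
            signal = [r for r in of_task if r.is_target]
            if mismatch is None:
                noise = [r for r in of_task if not r.is_target]
            else:
                noise = [r for r in of_task if r.mismatch_type == mismatch]
            c = _counts(signal, noise)
            if c.n_hit + c.n_miss < 1 or c.n_fa + c.n_cr < 1:
                warnings.warn(
                    f"session {sess!r}: no trials for contrast {name!r}; skipped"
                )
                continue
            rows.append(
                {
                    "session": sess,
                    "contrast": name,
                    "dprime": dprime(c),
                    "n_signal": c.n_hit + c.n_miss,
                    "n_noise": c.n_fa + c.n_cr,
                }
            )
    return pd.DataFrame(rows, columns=["session", "contrast", "dprime", "n_signal", "n_noise"])


#: paired comparisons evaluated across sessions
SESSION_COMPARISONS = [
    ("conjunction_color", "conjunction_complete"),
    ("conjunction_motion", "conjunction_complete"),
    ("conjunction_color", "conjunction_motion"),
    ("color_task", "conjunction_color"),
    ("motion_task", "conjunction_motion"),
]


def session_contrast_tests(
    summary: pd.DataFrame, alpha: float = BONFERRONI_ALPHA
) -> pd.DataFrame:
    """Paired t-tests of session-wise d' between contrasts.

    Sessions missing either contrast are dropped pairwise.  With fewer than
    two complete sessions the test is skipped with a warning.
    """
    wide = summary.pivot(index="session", columns="contrast", values="dprime")
    rows = []
    for a, b in SESSION_COMPARISONS:
        if a not in wide.columns or b not in wide.columns:
            warnings.warn(f"comparison {a} vs {b} skipped: contrast missing")
            continue
        paired = wide[[a, b]].dropna()
        if len(paired) < 2:
            warnings.warn(f"comparison {a} vs {b} skipped: fewer than 2 sessions")
            continue
        t, p = stats.ttest_rel(paired[a], paired[b])
        rows.append(
            {
                "contrast_a": a,
                "contrast_b": b,
                "mean_diff": float((paired[a] - paired[b]).mean()),
                "t": float(t),
                "p": float(p),
                "n_sessions": len(paired),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contrast_a", "contrast_b", "mean_diff", "t", "p", "n_sessions", "significant"],
    )


@dataclass(frozen=True)
class RTComparison:
    """Two-sample RT comparison on speed, raw and rank scales."""

    t_speed: float
    p_speed: float
    t_raw: float
    p_raw: float
    stat_rank: float
    p_rank: float
    n_a: int
    n_b: int
    median_a_ms: float
    median_b_ms: float

    def significant(self, alpha: float = BONFERRONI_ALPHA) -> bool:
        return self.p_speed < alpha


def rt_compare(rts_a: Sequence[float], rts_b: Sequence[float]) -> RTComparison:
    """Compare two reaction-time groups.

    The primary test is a two-sample t-test on speeds (1000/RT); the raw-ms
    t-test and the rank-sum test are reported alongside.  Note the sign of
    the speed-scale statistic is opposite to the raw-ms one: faster
    responses mean higher speed.
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 reaction times")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("reaction times must be positive")
    sa, sb = 1000.0 / a, 1000.0 / b
    t_s, p_s = stats.ttest_ind(sa, sb)
    t_r, p_r = stats.ttest_ind(a, b)
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: rank test is degenerate, report the trivial result
        w, p_w = 0.0, 1.0
    else:
        w, p_w = stats.ranksums(a, b)
    return RTComparison(
        t_speed=float(t_s), p_speed=float(p_s),
        t_raw=float(t_r), p_raw=float(p_r),
        stat_rank=float(w), p_rank=float(p_w),
        n_a=len(a), n_b=len(b),
        median_a_ms=float(np.median(a)), median_b_ms=float(np.median(b)),
    )


def rt_quartiles(rts: Sequence[float]) -> tuple[float, float, float]:
    """Median with first-third quartile range (the error-bar convention)."""
    a = np.asarray(rts, dtype=float)
    q1, q2, q3 = np.percentile(a, [25, 50, 75])
    return float(q1), float(q2), float(q3)
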