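"""Display-only series and figures for decoding results.

Everything here is for visualization, never for statistics: the moving
average smooths the plotted trace (28 ms window, 7 bins on the 4 ms grid),
the shuffle band shows where chance performance lives, and the cumulative
reaction-time overlay relates decoding latencies to the animal's responses.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import DecodingTimecourse
from .inference import NullEnsemble, SignificanceTrace
from .task import TrialRecord


def moving_average_ci(
    timecourse: DecodingTimecourse, window_ms: float = 28.0, ci: float = 0.95
) -> pd.DataFrame:
    """Centered moving average of the fold-mean with a fold-wise CI.

    The kernel covers ``window_ms`` of bin width (7 bins for 28 ms at 4 ms
    spacing).  Edges use the partial window, so a constant trace is
    reproduced exactly and interior spike mass is conserved.  The CI is a
    t-interval across folds of the smoothed per-fold traces.
    """
    d = np.diff(timecourse.time_ms)
    if len(d) == 0 or not np.allclose(d, d[0]):
        raise ValueError("time axis must be uniform")
    n_k = max(int(round(window_ms / d[0])), 1)
    kernel = np.ones(n_k)

    def smooth(row: np.ndarray) -> np.ndarray:
        num = np.convolve(row, kernel, mode="same")
        den = np.convolve(np.ones_like(row), kernel, mode="same")
        return num / den

    sm_folds = np.apply_along_axis(smooth, 1, timecourse.accuracies)
    mean = sm_folds.mean(axis=0)
    sem = sm_folds.std(axis=0, ddof=1) / np.sqrt(timecourse.n_folds)
    tcrit = stats.t.ppf(0.5 + ci / 2, df=timecourse.n_folds - 1)
    return pd.DataFrame(
        {
            "time_ms": timecourse.time_ms,
            "smoothed": mean,
            "ci_low": mean - tcrit * sem,
            "ci_high": mean + tcrit * sem,
        }
    )


def null_band(
    ensemble: NullEnsemble, level: float = 0.999, method: str = "normal"
) -> pd.DataFrame:
    """Per-bin chance band of the shuffle distribution.

    ``method="normal"`` uses mean ± z·SD at the requested level, which
    realizes the nominal coverage from a few hundred runs; ``"percentile"``
    takes empirical percentiles (at 100–500 runs these clamp to the extreme
    order statistics and under-cover the nominal level).
    """
    if ensemble.accuracies.size == 0:
        raise ValueError("empty ensemble")
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        sd = ensemble.accuracies.std(axis=0, ddof=1)
        lo = ensemble.mean - z * sd
        hi = ensemble.mean + z * sd
    elif method == "percentile":
        tail = (1 - level) / 2 * 100
        lo, hi = np.percentile(ensemble.accuracies, [tail, 100 - tail], axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {"time_ms": ensemble.time_ms, "band_low": lo, "band_high": hi,
         "null_mean": ensemble.mean}
    )


def cumulative_rt_overlay(
    trial_records: Sequence[TrialRecord],
    group: Optional[Sequence[int]] = None,
    floor_ms: float = 300.0,
) -> pd.DataFrame:
    """Cumulative fraction of responded trials vs time since test onset.

    ``group`` optionally restricts to the given trial ids.  100% equals all
    trials of the group that carry a button press; the ``floor_ms`` column
    marks the fastest admissible reaction time.
    """
    ids = None if group is None else set(group)
    rts = sorted(
        r.reaction_time_ms
        for r in trial_records
        if r.reaction_time_ms is not None and (ids is None or r.trial_id in ids)
    )
    if not rts:
        raise ValueError("no reaction times in the requested group")
    t = np.asarray(rts)
    frac = np.arange(1, len(t) + 1) / len(t)
    return pd.DataFrame({"time_ms": t, "cum_fraction": frac, "floor_ms": floor_ms})


def plot_timecourse(
    timecourse: DecodingTimecourse,
    null: Optional[NullEnsemble] = None,
    trace: Optional[SignificanceTrace] = None,
    onset_ms: Optional[float] = None,
    ax=None,
    label: Optional[str] = None,
    color: str = "tab:green",
):
    """Standard decoding figure: smoothed trace, CI, chance band, onset."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sm = moving_average_ci(timecourse)
    ax.fill_between(sm.time_ms, sm.ci_low, sm.ci_high, alpha=0.3, color=color, lw=0)
    ax.plot(sm.time_ms, sm.smoothed, color=color, label=label or timecourse.name)
    if null is not None:
        nb = null_band(null)
        ax.fill_between(nb.time_ms, nb.band_low, nb.band_high, alpha=0.25,
                        color="grey", lw=0, label="chance (99.9%)")
    if trace is not None and trace.significant.any():
        y0 = ax.get_ylim()[0]
        ax.plot(timecourse.time_ms[trace.significant],
                np.full(trace.significant.sum(), y0), ".", color=color, ms=3)
    if onset_ms is not None:
        ax.axvline(onset_ms, color=color, ls="--", lw=1)
    ax.axhline(timecourse.chance_level, color="k", ls=":", lw=1)
    ax.set_xlabel("time from event (ms)")
    ax.set_ylabel("decoding accuracy")
    ax.legend(frameon=False, fontsize=8)
    return ax
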