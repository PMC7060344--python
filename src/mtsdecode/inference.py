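"""Permutation-null significance, onset latency and condition contrasts.

Significance of decoding is judged against an empirical null built by
re-running the entire analysis — including the random balancing exclusions,
the cross-validation split and the pseudo-trial groupings — with the labels
of the averaged training pseudo-trials uniformly shuffled.  Observed
performance is compared to the null with a z-statistic per time bin
(one-sided, above chance); the normal approximation is the only way a
p-threshold of 1e-4 can be evaluated from a few hundred permutation runs.

The onset of decoding is the center of the earliest 40 ms window in which
*every* time bin is individually significant; on the 4 ms analysis grid
that window spans 11 bins inclusive, so onsets land on the grid.

Between-condition contrasts compare the two groups of testing-fold
accuracies bin-wise with two-sample t-tests at a Bonferroni-corrected
alpha (0.0167 for three pairwise task comparisons) and report maximal runs
of significant bins at least 40 ms long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .decoding import (
    DecoderSpec,
    DecodingTimecourse,
    LabeledDataset,
    balance_trials,
    decode_timecourse,
)

ALPHA_DECODING = 1e-4
ALPHA_CONTRAST = 0.05 / 3.0      # Bonferroni over three pairwise comparisons
ONSET_WINDOW_MS = 40.0
N_PERM_DEFAULT = 500


@dataclass
class NullEnsemble:
    """Fold-averaged accuracy traces from label-shuffled re-runs."""

    accuracies: np.ndarray           # (n_perm, n_bins)
    time_ms: np.ndarray
    seeds: np.ndarray                # (n_perm,) per-run child seeds
    name: str = "null"

    @property
    def n_perm(self) -> int:
        return self.accuracies.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.accuracies.std(axis=0, ddof=1)


@dataclass
class SignificanceTrace:
    """Per-bin z, one-sided p and significance flags at ``alpha``."""

    time_ms: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class OnsetEstimate:
    """Earliest sustained-significance latency, or absent."""

    onset_ms: Optional[float]
    window_ms: float = ONSET_WINDOW_MS
    bin_ms: float = 4.0

    @property
    def detected(self) -> bool:
        return self.onset_ms is not None


@dataclass
class ConditionContrast:
    """Bin-wise fold-accuracy contrast between two decoding conditions."""

    time_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    epochs: list[tuple[float, float]]     # maximal significant runs >= 40 ms
    onset_ms: Optional[float]             # center of the earliest such run
    fold_onsets_a: Optional[list[Optional[float]]] = None
    fold_onsets_b: Optional[list[Optional[float]]] = None
    onset_t: Optional[float] = None
    onset_p: Optional[float] = None


def run_balanced_decoding(
    dataset: LabeledDataset,
    spec: DecoderSpec = DecoderSpec(),
    seed: int = 0,
    *,
    shuffle_train_labels: bool = False,
    allow_small: bool = False,
) -> DecodingTimecourse:
    """Balance (seeded), then decode — one complete analysis run."""
    rng = np.random.default_rng(seed)
    bal_seed = int(rng.integers(0, 2**31))
    dec_seed = int(rng.integers(0, 2**31))
    idx = balance_trials(dataset.labels, dataset.covariates, seed=bal_seed)
    sub = dataset.subset(idx)
    return decode_timecourse(
        sub, spec, dec_seed,
        shuffle_train_labels=shuffle_train_labels, allow_small=allow_small,
    )


def permutation_null(
    dataset: LabeledDataset,
    spec: DecoderSpec = DecoderSpec(),
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    *,
    allow_small: bool = False,
) -> NullEnsemble:
    """Build the shuffled-label null ensemble.

    Each of the ``n_perm`` runs independently re-draws the balancing
    exclusions, the stratified split and the pseudo-trial groupings, then
    permutes the training pseudo-trial labels before fitting.  Test labels
    are untouched, so each run's fold-averaged trace is one draw from the
    chance distribution of the full analysis.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2**31)
    rows = []
    for s in child_seeds:
        tc = run_balanced_decoding(
            dataset, spec, int(s), shuffle_train_labels=True, allow_small=allow_small
        )
        rows.append(tc.mean)
    return NullEnsemble(
        accuracies=np.asarray(rows),
        time_ms=dataset.epochs.time_ms.copy(),
        seeds=child_seeds.astype(np.int64),
        name=f"{dataset.name}:null",
    )


def significance_trace(
    timecourse: DecodingTimecourse,
    null: NullEnsemble,
    alpha: float = ALPHA_DECODING,
) -> SignificanceTrace:
    """One-sided z-test of the observed trace against the null per bin."""
    if len(timecourse.time_ms) != len(null.time_ms) or not np.allclose(
        timecourse.time_ms, null.time_ms
    ):
        raise ValueError("timecourse and null must share the time axis")
    sd = null.sd
    if np.any(sd <= 0):
        bad = timecourse.time_ms[np.flatnonzero(sd <= 0)[0]]
        raise ValueError(f"degenerate null (zero SD) at {bad:g} ms")
    z = (timecourse.mean - null.mean) / sd
    p = stats.norm.sf(z)
    return SignificanceTrace(
        time_ms=timecourse.time_ms.copy(),
        z=z,
        p=p,
        significant=p < alpha,
        alpha=alpha,
    )


def _window_bins(time_ms: np.ndarray, window_ms: float) -> int:
    d = np.diff(time_ms)
    if len(d) == 0 or np.any(d <= 0) or not np.allclose(d, d[0]):
        raise ValueError("time axis must be uniform and increasing")
    bin_ms = float(d[0])
    n = int(round(window_ms / bin_ms)) + 1   # inclusive of both end bins
    if n < 2:
        raise ValueError(f"window {window_ms} ms spans fewer than 2 bins")
    return n


def detect_onset(
    trace: SignificanceTrace, window_ms: float = ONSET_WINDOW_MS
) -> OnsetEstimate:
    """Center of the earliest window with all bins significant, else absent."""
    n = _window_bins(trace.time_ms, window_ms)
    sig = np.asarray(trace.significant, dtype=bool)
    bin_ms = float(trace.time_ms[1] - trace.time_ms[0])
    for start in range(0, len(sig) - n + 1):
        if sig[start : start + n].all():
            center = trace.time_ms[start] + (n - 1) / 2.0 * bin_ms
            return OnsetEstimate(float(center), window_ms, bin_ms)
    return OnsetEstimate(None, window_ms, bin_ms)


def fold_onsets(
    timecourse: DecodingTimecourse,
    null: NullEnsemble,
    alpha: float = ALPHA_DECODING,
    window_ms: float = ONSET_WINDOW_MS,
) -> list[Optional[float]]:
    """Onset per testing fold, each judged against the fold-averaged null.

    Folds without a qualifying sustained-significance window yield ``None``
    and are excluded (with a warning) from downstream distribution tests.
    """
    sd = null.sd
    if np.any(sd <= 0):
        raise ValueError("degenerate null (zero SD)")
    out: list[Optional[float]] = []
    for f in range(timecourse.n_folds):
        z = (timecourse.accuracies[f] - null.mean) / sd
        p = stats.norm.sf(z)
        tr = SignificanceTrace(
            time_ms=timecourse.time_ms, z=z, p=p, significant=p < alpha, alpha=alpha
        )
        out.append(detect_onset(tr, window_ms).onset_ms)
    n_missing = sum(o is None for o in out)
    if n_missing:
        warnings.warn(
            f"{n_missing} of {timecourse.n_folds} folds have no qualifying "
            f"{window_ms:g} ms significance window"
        )
    return out


def compare_fold_onsets(
    onsets_a: Sequence[Optional[float]], onsets_b: Sequence[Optional[float]]
) -> tuple[Optional[float], Optional[float]]:
    """Two-sample t-test on the per-fold onset distributions.

    Returns ``(t, p)``, or ``(None, None)`` when either condition has fewer
    than two folds with an onset (the comparison is then skipped, mirroring
    conditions where not every fold reaches sustained significance).
    """
    a = [o for o in onsets_a if o is not None]
    b = [o for o in onsets_b if o is not None]
    if len(a) < 2 or len(b) < 2:
        warnings.warn("fold-onset comparison skipped: fewer than 2 onsets in a group")
        return None, None
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def _significant_runs(
    sig: np.ndarray, time_ms: np.ndarray, min_bins: int
) -> list[tuple[float, float]]:
    runs = []
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_bins:
                runs.append((float(time_ms[start]), float(time_ms[i - 1])))
            start = None
    return runs


def compare_conditions(
    tc_a: DecodingTimecourse,
    tc_b: DecodingTimecourse,
    alpha: float = ALPHA_CONTRAST,
    window_ms: float = ONSET_WINDOW_MS,
    *,
    null_a: Optional[NullEnsemble] = None,
    null_b: Optional[NullEnsemble] = None,
) -> ConditionContrast:
    """Bin-wise fold-accuracy contrast with a minimum-duration run criterion.

    Fold accuracies are treated as independent samples in the two-sample
    t-test (a deliberately simple convention; its optimism is documented,
    not corrected).  When both nulls are supplied, per-fold onsets are also
    compared between conditions.
    """
    if len(tc_a.time_ms) != len(tc_b.time_ms) or not np.allclose(
        tc_a.time_ms, tc_b.time_ms
    ):
        raise ValueError("conditions must share the time axis")
    n_bins = len(tc_a.time_ms)
    t = np.zeros(n_bins)
    p = np.ones(n_bins)
    for b in range(n_bins):
        a_col = tc_a.accuracies[:, b]
        b_col = tc_b.accuracies[:, b]
        if np.ptp(a_col) == 0 and np.ptp(b_col) == 0 and a_col[0] == b_col[0]:
            continue  # identical constant columns: no difference
        t[b], p[b] = stats.ttest_ind(a_col, b_col)
    sig = p < alpha
    n = _window_bins(tc_a.time_ms, window_ms)
    epochs = _significant_runs(sig, tc_a.time_ms, n)
    onset = None
    if epochs:
        bin_ms = float(tc_a.time_ms[1] - tc_a.time_ms[0])
        onset = epochs[0][0] + (n - 1) / 2.0 * bin_ms

    oa = ob = None
    onset_t = onset_p = None
    if null_a is not None and null_b is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oa = fold_onsets(tc_a, null_a, window_ms=window_ms)
            ob = fold_onsets(tc_b, null_b, window_ms=window_ms)
        onset_t, onset_p = compare_fold_onsets(oa, ob)
    return ConditionContrast(
        time_ms=tc_a.time_ms.copy(),
        t=t,
        p=p,
        significant=sig,
        alpha=alpha,
        epochs=epochs,
        onset_ms=onset,
        fold_onsets_a=oa,
        fold_onsets_b=ob,
        onset_t=onset_t,
        onset_p=onset_p,
    )
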