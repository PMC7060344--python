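"""Covariate-balanced, cross-validated, time-resolved population decoding.

The analysis contract, stage by stage:

1. ``balance_trials`` — every cell of the label × covariate cross-tabulation
   is subsampled to the minimum cell count, so the label is exactly
   independent of every nuisance variable and chance equals the reciprocal
   of the number of classes.
2. ``make_splits`` — stratified 20-fold partition; each trial appears in
   exactly one test set and class counts are balanced per fold up to a
   remainder of one.
3. ``window_features`` — per time bin, all channels over a window of
   ±2 samples around the bin (clipped at epoch edges) are concatenated.
4. ``average_pseudotrials`` — training trials of the same class are randomly
   partitioned into groups of five and averaged; a remainder group of at
   least two is averaged, a singleton passes through.  Test trials are
   never averaged.
5. A linear SVM (C = 1, one-vs-one voting) is fit per fold and time bin on
   the standardized pseudo-trials and scored on single left-out trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from . import _svm
from .preprocessing import EpochedData


class BalanceError(ValueError):
    """Raised when a label x covariate cell is empty in strict mode."""


@dataclass(frozen=True)
class DecoderSpec:
    """Classifier and cross-validation settings."""

    C: float = 1.0
    window_radius: int = 2          # samples on each side of the bin
    pseudo_trial_group: int = 5
    n_folds: int = 20
    standardize: bool = True
    backend: str = "numba"          # "numba" | "sklearn" (reference path)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")
        if self.pseudo_trial_group < 1:
            raise ValueError("pseudo_trial_group must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.backend not in ("numba", "sklearn"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class LabeledDataset:
    """Epochs plus one decoding label and nuisance covariates per trial."""

    epochs: EpochedData
    labels: np.ndarray               # (n_trials,) arbitrary hashable values
    covariates: Optional[np.ndarray] = None   # (n_trials, n_covariates)
    name: str = "decoding"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.epochs.n_trials:
            raise ValueError("labels length must match number of epochs")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != len(self.labels):
                raise ValueError("covariates length must match number of epochs")

    @property
    def class_names(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_classes

    @property
    def encoded_labels(self) -> np.ndarray:
        return np.searchsorted(self.class_names, self.labels)

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            epochs=self.epochs.select(np.asarray(indices)),
            labels=self.labels[indices],
            covariates=None if self.covariates is None else self.covariates[indices],
            name=self.name,
        )


@dataclass
class DecodingTimecourse:
    """Per-fold, per-time-bin accuracies for one decoding analysis."""

    time_ms: np.ndarray              # (n_bins,)
    accuracies: np.ndarray           # (n_folds, n_bins) in [0, 1]
    n_classes: int
    class_names: np.ndarray
    seed: int
    spec: DecoderSpec
    name: str = "decoding"

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def n_folds(self) -> int:
        return self.accuracies.shape[0]

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_classes


def balance_trials(
    labels: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    seed: int = 0,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Indices of a subsample with exactly equal label × covariate cells.

    Every cell of the cross-tabulation of the label with the joint covariate
    value is reduced to the global minimum cell count by seeded uniform
    subsampling.  In strict mode an empty cell (a label missing for some
    observed covariate combination) raises :class:`BalanceError` naming the
    cell; with ``strict=False`` such covariate combinations are dropped.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise BalanceError("no trials to balance")
    classes = np.unique(labels)
    if covariates is None:
        cov_keys = np.zeros(len(labels), dtype=int)
        combos = [()]
        combo_of = {(): 0}
    else:
        cov = np.asarray(covariates)
        if cov.ndim == 1:
            cov = cov[:, None]
        combos_list = [tuple(row) for row in cov]
        combos = sorted(set(combos_list))
        combo_of = {c: i for i, c in enumerate(combos)}
        cov_keys = np.array([combo_of[c] for c in combos_list])

    rng = np.random.default_rng(seed)
    cells: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, int] = {}
    for ci, combo in enumerate(combos):
        for cls in classes:
            idx = np.flatnonzero((labels == cls) & (cov_keys == ci))
            cells[(cls, combo)] = idx
            counts[(cls, combo)] = len(idx)

    empty = [k for k, n in counts.items() if n == 0]
    if empty:
        if strict:
            cls, combo = empty[0]
            combo_str = ", ".join(str(c) for c in combo) or "none"
            raise BalanceError(
                f"empty cell: label={str(cls)!r}, covariates=({combo_str}) "
                f"({len(empty)} empty cell(s) total)"
            )
        bad_combos = {combo for _, combo in empty}
        cells = {k: v for k, v in cells.items() if k[1] not in bad_combos}
        if not cells:
            raise BalanceError("all covariate cells empty after dropping")

    m = min(len(v) for v in cells.values())
    keep: list[np.ndarray] = []
    for key in sorted(cells, key=lambda k: (str(k[0]), str(k[1]))):
        idx = cells[key]
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def make_splits(
    labels: np.ndarray, n_folds: int, seed: int, *, allow_small: bool = False
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split; every trial appears in exactly one test set."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    classes, cnt = np.unique(labels, return_counts=True)
    if cnt.min() < n_folds:
        if not allow_small:
            raise ValueError(
                f"smallest class has {cnt.min()} trials < n_folds={n_folds}; "
                "pass allow_small=True to permit folds with missing classes"
            )
        # manual stratified assignment: cyclic fill keeps fold sizes within
        # one of each other even when a class has fewer members than folds
        rng = np.random.default_rng(seed)
        fold_of = np.empty(len(labels), dtype=int)
        offset = 0
        for cls in classes:
            members = rng.permutation(np.flatnonzero(labels == cls))
            for i, m in enumerate(members):
                fold_of[m] = (offset + i) % n_folds
            offset += len(members)
        return [
            (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
            for f in range(n_folds)
        ]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    return [(np.asarray(tr), np.asarray(te)) for tr, te in skf.split(labels, labels)]


def window_features(
    epochs: Union[EpochedData, np.ndarray], bin_index: int, radius: int
) -> np.ndarray:
    """Trials × features matrix for one time bin.

    Features are all channels over the window ``[bin-radius, bin+radius]``
    clipped at the epoch edges, concatenated channel-major: feature
    ``c * width + s`` is channel ``c`` at window sample ``s``.
    """
    data = epochs.data if isinstance(epochs, EpochedData) else np.asarray(epochs)
    n_trials, n_ch, n_bins = data.shape
    if not 0 <= bin_index < n_bins:
        raise IndexError(f"bin_index {bin_index} out of range 0..{n_bins - 1}")
    lo = max(bin_index - radius, 0)
    hi = min(bin_index + radius + 1, n_bins)
    return data[:, :, lo:hi].reshape(n_trials, n_ch * (hi - lo)).astype(float)


def group_assignments(
    labels: np.ndarray, group_size: int, rng: np.random.Generator
) -> list[tuple[int, np.ndarray]]:
    """Random within-class partition into averaging groups.

    Returns ``(class_label, member_positions)`` per group.  Positions index
    into ``labels``.  The last chunk of a class keeps whatever size remains:
    a remainder of two or more becomes an averaged group, a singleton passes
    through as its own (trivially averaged) group.
    """
    labels = np.asarray(labels)
    out: list[tuple[int, np.ndarray]] = []
    for cls in np.unique(labels):
        pos = np.flatnonzero(labels == cls)
        if len(pos) == 0:
            raise ValueError(f"empty class {cls!r}")
        pos = rng.permutation(pos)
        for start in range(0, len(pos), group_size):
            out.append((int(cls), pos[start : start + group_size]))
    return out


def average_pseudotrials(
    features: np.ndarray, labels: np.ndarray, group_size: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average randomly grouped same-class trials into pseudo-trials."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    groups = group_assignments(labels, group_size, rng)
    out_x = np.stack([features[m].mean(axis=0) for _, m in groups])
    out_y = np.asarray([c for c, _ in groups])
    return out_x, out_y


def _flatten_groups(
    enc_labels: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    group_size: int,
    rng: np.random.Generator,
    shuffle_train_labels: bool,
):
    """Build the flat per-fold group arrays the jitted kernel consumes."""
    n_trials = len(enc_labels)
    fold_of = np.full(n_trials, -1, dtype=np.int64)
    member_idx: list[int] = []
    m_start = [0]
    group_label: list[int] = []
    gf_start = [0]
    for f, (train, test) in enumerate(splits):
        fold_of[test] = f
        groups = group_assignments(enc_labels[train], group_size, rng)
        glabs = np.asarray([c for c, _ in groups], dtype=np.int64)
        if shuffle_train_labels:
            glabs = rng.permutation(glabs)
        for (cls, members), lab in zip(groups, glabs):
            member_idx.extend(train[members].tolist())
            m_start.append(len(member_idx))
            group_label.append(int(lab))
        gf_start.append(len(group_label))
    return (
        fold_of,
        np.asarray(member_idx, dtype=np.int64),
        np.asarray(m_start, dtype=np.int64),
        np.asarray(group_label, dtype=np.int64),
        np.asarray(gf_start, dtype=np.int64),
    )


def decode_timecourse(
    dataset: LabeledDataset,
    spec: DecoderSpec = DecoderSpec(),
    seed: int = 0,
    *,
    shuffle_train_labels: bool = False,
    allow_small: bool = False,
) -> DecodingTimecourse:
    """Run the full windowed, cross-validated decoding analysis.

    The dataset is expected to be balanced already (see
    :func:`balance_trials`); chance is ``1 / n_classes``.  With
    ``shuffle_train_labels=True`` the labels of the averaged training
    pseudo-trials are uniformly permuted before fitting (test labels are
    untouched) — the permutation-null primitive.  Identical inputs and seed
    give identical output.
    """
    rng = np.random.default_rng(seed)
    enc = dataset.encoded_labels.astype(np.int64)
    split_seed = int(rng.integers(0, 2**31))
    splits = make_splits(enc, spec.n_folds, split_seed, allow_small=allow_small)
    fold_of, member_idx, m_start, group_label, gf_start = _flatten_groups(
        enc, splits, spec.pseudo_trial_group, rng, shuffle_train_labels
    )
    X = np.ascontiguousarray(dataset.epochs.data, dtype=np.float64)
    if spec.backend == "numba":
        acc = _svm.decode_kernel(
            X, enc, fold_of, spec.n_folds, member_idx, m_start, group_label,
            gf_start, dataset.n_classes, spec.window_radius, spec.C,
            spec.standardize,
        )
    else:
        acc = _decode_python(
            X, enc, fold_of, spec, member_idx, m_start, group_label, gf_start,
            dataset.n_classes,
        )
    return DecodingTimecourse(
        time_ms=dataset.epochs.time_ms.copy(),
        accuracies=acc,
        n_classes=dataset.n_classes,
        class_names=dataset.class_names,
        seed=seed,
        spec=spec,
        name=dataset.name,
    )


def _decode_python(
    X, enc, fold_of, spec, member_idx, m_start, group_label, gf_start, n_classes
):
    """Reference implementation over sklearn's LinearSVC (slow path)."""
    n_trials, n_ch, n_bins = X.shape
    acc = np.zeros((spec.n_folds, n_bins))
    for f in range(spec.n_folds):
        test = np.flatnonzero(fold_of == f)
        if len(test) == 0:
            continue
        g0, g1 = gf_start[f], gf_start[f + 1]
        glab = group_label[g0:g1]
        members = [member_idx[m_start[g] : m_start[g + 1]] for g in range(g0, g1)]
        for b in range(n_bins):
            F = window_features(X, b, spec.window_radius)
            Gmat = np.stack([F[m].mean(axis=0) for m in members])
            Tmat = F[test]
            if spec.standardize:
                mu = Gmat.mean(axis=0)
                sd = Gmat.std(axis=0)
                sd[sd < 1e-12] = 1.0
                Gmat = (Gmat - mu) / sd
                Tmat = (Tmat - mu) / sd
            pred = _svm.sklearn_fit_predict(Gmat, glab, Tmat, C=spec.C)
            acc[f, b] = np.mean(pred == enc[test])
    return acc


def single_channel_timecourses(
    dataset: LabeledDataset,
    spec: DecoderSpec = DecoderSpec(),
    seed: int = 0,
    *,
    allow_small: bool = False,
) -> np.ndarray:
    """Decode from each channel alone: (channels, folds, bins) accuracies.

    Every channel uses the same seed, hence the same balancing, splits and
    groupings, so channels differ only in the features they contribute —
    the map is directly comparable across the array.
    """
    n_ch = dataset.epochs.data.shape[1]
    out = []
    for c in range(n_ch):
        sub = LabeledDataset(
            epochs=dataset.epochs.select_channels([c]),
            labels=dataset.labels,
            covariates=dataset.covariates,
            name=f"{dataset.name}[ch{c}]",
        )
        tc = decode_timecourse(sub, spec, seed, allow_small=allow_small)
        out.append(tc.accuracies)
    return np.stack(out)
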