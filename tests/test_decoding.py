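"""Balancing, splitting, windowing, pseudo-trials and the decoding engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from mtsdecode._svm import dcd_fit
from mtsdecode.decoding import (
    BalanceError,
    DecoderSpec,
    LabeledDataset,
    average_pseudotrials,
    balance_trials,
    decode_timecourse,
    make_splits,
    single_channel_timecourses,
    window_features,
)

from conftest import make_noise_epochs


def noise_dataset(n_per_class, classes, n_ch=6, n_bins=12, seed=0):
    n = n_per_class * classes
    ep = make_noise_epochs(n, n_ch, n_bins, seed=seed)
    return LabeledDataset(ep, np.repeat(np.arange(classes), n_per_class))


def signal_dataset(n_per_class=32, n_ch=8, n_bins=30, onset_bin=15, amp=4.0, seed=0):
    """Noise plus a class-specific channel pattern from ``onset_bin`` on."""
    classes = 4
    ds = noise_dataset(n_per_class, classes, n_ch, n_bins, seed=seed)
    rng = np.random.default_rng(seed + 1)
    patterns = np.linalg.qr(rng.normal(size=(n_ch, classes)))[0].T * np.sqrt(n_ch)
    data = ds.epochs.data.astype(np.float32)
    for i, lab in enumerate(ds.labels):
        data[i, :, onset_bin:] += (amp * patterns[lab])[:, None]
    ds.epochs.data = data
    return ds


class TestBalancing:
    def test_two_classes_without_covariates(self):
        labels = np.array(["A"] * 30 + ["B"] * 20)
        idx = balance_trials(labels, seed=0)
        assert len(idx) == 40
        assert (labels[idx] == "A").sum() == 20

    def test_min_cell_rule_with_covariate(self):
        labels = np.array(["hit"] * 20 + ["cr"] * 20)
        colors = np.array(
            ["red"] * 8 + ["blue"] * 12 + ["red"] * 10 + ["blue"] * 10
        )
        idx = balance_trials(labels, colors, seed=1)
        assert len(idx) == 32
        for lab in ("hit", "cr"):
            for col in ("red", "blue"):
                assert ((labels[idx] == lab) & (colors[idx] == col)).sum() == 8

    def test_label_independent_of_covariate_exactly(self):
        """Chi-square association on the retained cross-tab is exactly 0."""
        rng = np.random.default_rng(2)
        labels = rng.choice(["a", "b", "c"], size=300)
        cov = rng.choice(["x", "y"], size=300)
        idx = balance_trials(labels, cov, seed=3)
        tab = np.array(
            [
                [((labels[idx] == l) & (cov[idx] == c)).sum() for c in ("x", "y")]
                for l in ("a", "b", "c")
            ]
        )
        stat, _, _, _ = chi2_contingency(tab)
        assert stat == 0.0

    def test_empty_cell_error_names_cell(self):
        labels = np.array(["hit"] * 5 + ["cr"] * 5)
        cov = np.array(["red"] * 5 + ["blue"] * 5)  # hits only red
        with pytest.raises(BalanceError, match="label='hit'.*blue"):
            balance_trials(labels, cov, seed=0)

    def test_drop_cell_mode(self):
        labels = np.array(["hit"] * 5 + ["cr"] * 8)
        cov = np.array(["red"] * 5 + ["blue"] * 5 + ["red"] * 3)
        idx = balance_trials(labels, cov, seed=0, strict=False)
        # blue column has no hits -> dropped entirely; red min cell = 3
        assert set(cov[idx]) == {"red"}
        assert (labels[idx] == "hit").sum() == (labels[idx] == "cr").sum() == 3

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        labels = rng.choice([0, 1], size=100)
        a = balance_trials(labels, seed=9)
        b = balance_trials(labels, seed=9)
        assert np.array_equal(a, b)


class TestSplits:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n_per_class=st.integers(20, 40),
        n_classes=st.integers(2, 4),
        seed=st.integers(0, 10_000),
    )
    def test_partition_properties(self, n_per_class, n_classes, seed):
        """Test sets are disjoint, exhaustive, and class-balanced per fold
        up to a remainder of one."""
        labels = np.repeat(np.arange(n_classes), n_per_class)
        labels = np.random.default_rng(seed).permutation(labels)
        splits = make_splits(labels, 20, seed)
        all_test = np.concatenate([te for _, te in splits])
        assert len(all_test) == len(labels)
        assert len(np.unique(all_test)) == len(labels)
        for tr, te in splits:
            assert set(tr) & set(te) == set()
            assert len(set(tr) | set(te)) == len(labels)
            counts = np.bincount(labels[te], minlength=n_classes)
            assert counts.max() - counts.min() <= 1

    def test_class_smaller_than_folds_rejected(self):
        labels = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="n_folds"):
            make_splits(labels, 20, seed=0)
        splits = make_splits(labels, 20, seed=0, allow_small=True)
        assert len(splits) == 20
        assert all(len(te) >= 1 for _, te in splits)

    def test_same_seed_identical_folds(self):
        labels = np.repeat(np.arange(4), 10)
        a = make_splits(labels, 5, seed=3)
        b = make_splits(labels, 5, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)


class TestWindowFeatures:
    def test_matches_brute_force_slicing(self):
        """Oracle: explicit slice-and-concatenate per trial and channel."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(7, 3, 11))
        for radius in (0, 1, 2, 3):
            for b in range(11):
                got = window_features(data, b, radius)
                lo, hi = max(0, b - radius), min(11, b + radius + 1)
                expect = np.stack(
                    [np.concatenate([data[t, c, lo:hi] for c in range(3)]) for t in range(7)]
                )
                assert np.array_equal(got, expect), (b, radius)

    def test_feature_counts(self):
        data = np.zeros((2, 96, 50))
        assert window_features(data, 25, 2).shape == (2, 480)
        assert window_features(data, 0, 2).shape == (2, 288)   # clipped to width 3
        assert window_features(data, 25, 0).shape == (2, 96)

    def test_bad_bin_rejected(self):
        with pytest.raises(IndexError):
            window_features(np.zeros((1, 2, 5)), 5, 1)


class TestPseudoTrials:
    def test_exact_grouping(self):
        X = np.arange(50, dtype=float)[:, None]
        y = np.zeros(50, dtype=int)
        Xp, yp = average_pseudotrials(X, y, 5, seed=0)
        assert Xp.shape == (10, 1)
        assert np.all(yp == 0)

    def test_remainder_rule(self):
        """7 trials at group size 5: one group of 5 plus one averaged pair."""
        X = np.ones((7, 2))
        y = np.zeros(7, dtype=int)
        Xp, _ = average_pseudotrials(X, y, 5, seed=1)
        assert Xp.shape == (2, 2)

    def test_singleton_passes_through(self):
        X = np.arange(6, dtype=float)[:, None]
        y = np.zeros(6, dtype=int)
        Xp, _ = average_pseudotrials(X, y, 5, seed=2)
        assert Xp.shape == (2, 1)
        # one output is a 5-mean, the other a raw single trial
        assert any(float(v) == int(v) for v in Xp.ravel())

    def test_identical_vectors_unchanged(self):
        X = np.tile([3.0, -1.0], (15, 1))
        y = np.repeat([0, 1, 2], 5)
        Xp, yp = average_pseudotrials(X, y, 5, seed=3)
        assert np.allclose(Xp, [3.0, -1.0])
        assert sorted(yp) == [0, 1, 2]

    def test_mean_preserved_per_class(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        Xp, yp = average_pseudotrials(X, y, 5, seed=4)
        for cls in (0, 1):
            assert np.allclose(Xp[yp == cls].mean(axis=0), X[y == cls].mean(axis=0))


class TestSolver:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dcd_matches_liblinear_weights(self, seed):
        """Independent oracle: sklearn's LinearSVC (hinge, dual) on the same
        bias-augmented problem yields the same weight vector."""
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 15))
        y = np.where(rng.random(30) > 0.5, 1.0, -1.0)
        Xa = np.hstack([X, np.ones((30, 1))])
        w = np.empty(16)
        alpha = np.empty(30)
        dcd_fit(Xa, y, 1.0, w, alpha, 20000, 1e-9)
        ref = LinearSVC(
            C=1.0, loss="hinge", dual=True, fit_intercept=True,
            intercept_scaling=1.0, tol=1e-10, max_iter=500000,
        ).fit(X, y)
        expect = np.r_[ref.coef_[0], ref.intercept_]
        assert np.abs(w - expect).max() < 1e-5

    def test_backends_agree_on_timecourse(self):
        ds = signal_dataset(n_per_class=12, n_ch=4, n_bins=8, onset_bin=4, seed=7)
        spec_nb = DecoderSpec(n_folds=4, pseudo_trial_group=3)
        spec_sk = DecoderSpec(n_folds=4, pseudo_trial_group=3, backend="sklearn")
        a = decode_timecourse(ds, spec_nb, seed=11)
        b = decode_timecourse(ds, spec_sk, seed=11)
        assert np.abs(a.accuracies - b.accuracies).mean() < 0.02


class TestDecodeTimecourse:
    def test_signal_window_decoded_noise_window_at_chance(self):
        ds = signal_dataset()
        tc = decode_timecourse(ds, DecoderSpec(), seed=1)
        assert tc.mean[18:].mean() > 0.9
        early = tc.mean[:12].mean()
        assert abs(early - 0.25) < 0.08

    def test_shuffled_labels_at_chance_everywhere(self):
        ds = signal_dataset(seed=2)
        tc = decode_timecourse(ds, DecoderSpec(), seed=3, shuffle_train_labels=True)
        n = len(ds.labels)
        band = 2.58 * np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(tc.mean - 0.25) < band + 0.12)
        assert abs(tc.mean.mean() - 0.25) < 0.05

    def test_identical_class_distributions_near_half(self):
        """Two classes drawn from one distribution decode at ~0.5.  Single
        splits fluctuate (adjacent bins share window samples), so the check
        averages over replicates."""
        means = [
            decode_timecourse(noise_dataset(40, 2, seed=40 + r), DecoderSpec(), seed=50 + r)
            .mean.mean()
            for r in range(6)
        ]
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_channel_permutation_invariance(self):
        ds = signal_dataset(seed=6)
        perm = np.random.default_rng(0).permutation(ds.epochs.data.shape[1])
        ds_perm = LabeledDataset(
            ds.epochs.select_channels(perm), ds.labels, name=ds.name
        )
        a = decode_timecourse(ds, DecoderSpec(), seed=7)
        b = decode_timecourse(ds_perm, DecoderSpec(), seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_end_to_end_determinism(self):
        ds = signal_dataset(seed=8)
        a = decode_timecourse(ds, DecoderSpec(), seed=9)
        b = decode_timecourse(ds, DecoderSpec(), seed=9)
        assert np.array_equal(a.accuracies, b.accuracies)
        c = decode_timecourse(ds, DecoderSpec(), seed=10)
        assert not np.array_equal(a.accuracies, c.accuracies)

    def test_constant_features_fall_back_to_tie_break(self):
        ep = make_noise_epochs(40, 3, 6, seed=11)
        ep.data = np.zeros_like(ep.data)
        ds = LabeledDataset(ep, np.repeat([0, 1], 20))
        tc = decode_timecourse(ds, DecoderSpec(n_folds=5), seed=12)
        assert np.all((tc.accuracies >= 0) & (tc.accuracies <= 1))
        assert abs(tc.mean.mean() - 0.5) < 0.51  # defined, not NaN

    def test_accuracies_bounded_and_mean_consistent(self):
        ds = signal_dataset(seed=13)
        tc = decode_timecourse(ds, DecoderSpec(), seed=14)
        assert np.all((tc.accuracies >= 0) & (tc.accuracies <= 1))
        assert np.allclose(tc.mean, tc.accuracies.mean(axis=0))


class TestSingleChannel:
    def test_effect_localized_to_informative_channels(self):
        """Signal confined to channels 0-1: only those exceed chance; the
        population decoder is at least as good as the best single channel."""
        n_per, n_ch, n_bins = 30, 5, 10
        ds = noise_dataset(n_per, 2, n_ch, n_bins, seed=15)
        data = ds.epochs.data.astype(np.float32)
        for i, lab in enumerate(ds.labels):
            data[i, :2, 5:] += 4.0 * (1.0 if lab else -1.0)
        ds.epochs.data = data
        spec = DecoderSpec(n_folds=5)
        per_ch = single_channel_timecourses(ds, spec, seed=16)
        assert per_ch.shape == (n_ch, 5, n_bins)
        late = per_ch[:, :, 6:].mean(axis=(1, 2))
        assert late[0] > 0.9 and late[1] > 0.9
        assert np.all(np.abs(late[2:] - 0.5) < 0.2)
        pop = decode_timecourse(ds, spec, seed=16)
        assert pop.mean[6:].mean() >= late.max() - 0.02
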