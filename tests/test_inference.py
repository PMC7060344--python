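"""Permutation nulls, significance tracing, onsets and contrasts."""

import numpy as np
import pytest
from scipy.stats import norm

from mtsdecode.decoding import DecoderSpec, DecodingTimecourse, LabeledDataset
from mtsdecode.inference import (
    ConditionContrast,
    NullEnsemble,
    SignificanceTrace,
    compare_conditions,
    compare_fold_onsets,
    detect_onset,
    fold_onsets,
    permutation_null,
    run_balanced_decoding,
    significance_trace,
)

from conftest import make_noise_epochs

GRID = np.arange(-40.0, 360.0, 4.0)  # 100 bins


def fake_timecourse(mean_per_bin, n_folds=20, noise=0.0, seed=0, time_ms=None):
    t = GRID if time_ms is None else time_ms
    rng = np.random.default_rng(seed)
    acc = np.tile(np.asarray(mean_per_bin, dtype=float), (n_folds, 1))
    if noise:
        acc = acc + rng.normal(0, noise, acc.shape)
    return DecodingTimecourse(
        time_ms=t, accuracies=np.clip(acc, 0, 1), n_classes=4,
        class_names=np.array(list("abcd")), seed=seed, spec=DecoderSpec(),
    )


def fake_null(n_perm=100, mean=0.25, sd=0.02, seed=1, time_ms=None):
    t = GRID if time_ms is None else time_ms
    rng = np.random.default_rng(seed)
    return NullEnsemble(
        accuracies=rng.normal(mean, sd, size=(n_perm, len(t))),
        time_ms=t, seeds=np.arange(n_perm),
    )


def trace_from_mask(mask, time_ms=None):
    t = GRID if time_ms is None else time_ms
    mask = np.asarray(mask, dtype=bool)
    return SignificanceTrace(
        time_ms=t, z=np.where(mask, 10.0, 0.0),
        p=np.where(mask, 1e-12, 0.5), significant=mask, alpha=1e-4,
    )


class TestSignificanceTrace:
    def test_observed_at_null_mean_is_not_significant(self):
        null = fake_null(sd=0.02)
        tc = fake_timecourse(null.mean)
        tr = significance_trace(tc, null)
        assert np.allclose(tr.z, 0.0)
        assert np.allclose(tr.p, 0.5)
        assert not tr.significant.any()

    def test_five_sigma_exceeds_threshold(self):
        """Normal-tail oracle: p = norm.sf(5) ~ 2.9e-7 < 1e-4."""
        null = fake_null(sd=0.02, seed=2)
        tc = fake_timecourse(null.mean + 5.0 * null.sd)
        tr = significance_trace(tc, null)
        assert np.allclose(tr.p, norm.sf(5.0))
        assert tr.significant.all()

    def test_alpha_one_flags_everything(self):
        null = fake_null(seed=3)
        tc = fake_timecourse(null.mean)
        tr = significance_trace(tc, null, alpha=1.0)
        assert tr.significant.all()

    def test_degenerate_null_rejected(self):
        null = fake_null(sd=0.0, seed=4)
        null.accuracies[:] = 0.25
        tc = fake_timecourse(np.full(len(GRID), 0.3))
        with pytest.raises(ValueError, match="degenerate"):
            significance_trace(tc, null)

    def test_mismatched_time_axes_rejected(self):
        null = fake_null()
        tc = fake_timecourse(np.full(90, 0.25), time_ms=GRID[:90])
        with pytest.raises(ValueError, match="time axis"):
            significance_trace(tc, null)


class TestOnsetDetection:
    @staticmethod
    def brute_force_onset(sig, time_ms, window_ms=40.0):
        """Exhaustive scan oracle over every candidate window."""
        bin_ms = time_ms[1] - time_ms[0]
        n = int(round(window_ms / bin_ms)) + 1
        for s in range(len(sig) - n + 1):
            if all(sig[s : s + n]):
                return time_ms[s] + (n - 1) / 2 * bin_ms
        return None

    def test_significant_from_100ms_gives_onset_120(self):
        tr = trace_from_mask(GRID >= 100.0)
        assert detect_onset(tr).onset_ms == 120.0

    def test_isolated_bins_give_no_onset(self):
        mask = np.zeros(len(GRID), dtype=bool)
        mask[::7] = True
        assert detect_onset(trace_from_mask(mask)).onset_ms is None

    def test_fully_significant_trace_starts_at_left_edge(self):
        tr = trace_from_mask(np.ones(len(GRID), dtype=bool))
        assert detect_onset(tr).onset_ms == GRID[0] + 20.0

    def test_matches_exhaustive_scan_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            mask = rng.random(len(GRID)) < rng.uniform(0.3, 0.95)
            tr = trace_from_mask(mask)
            assert detect_onset(tr).onset_ms == self.brute_force_onset(mask, GRID)

    def test_window_must_span_two_bins(self):
        tr = trace_from_mask(np.ones(len(GRID), dtype=bool))
        with pytest.raises(ValueError, match="fewer than 2"):
            detect_onset(tr, window_ms=2.0)

    def test_gap_before_sustained_run_ignored(self):
        mask = (GRID >= 60.0) & (GRID < 80.0) | (GRID >= 140.0)
        tr = trace_from_mask(mask)
        assert detect_onset(tr).onset_ms == 160.0


class TestFoldOnsets:
    def test_homogeneous_strong_effect_gives_consistent_onsets(self):
        null = fake_null(sd=0.02, seed=6)
        mean = np.where(GRID >= 100.0, 0.9, 0.25)
        tc = fake_timecourse(mean, noise=0.01, seed=7)
        onsets = fold_onsets(tc, null)
        assert all(o is not None for o in onsets)
        assert np.ptp([o for o in onsets]) <= 8.0

    def test_injected_latency_difference_detected(self):
        null = fake_null(sd=0.02, seed=8)
        tc_a = fake_timecourse(np.where(GRID >= 100.0, 0.9, 0.25), noise=0.01, seed=9)
        tc_b = fake_timecourse(np.where(GRID >= 160.0, 0.9, 0.25), noise=0.01, seed=10)
        t, p = compare_fold_onsets(fold_onsets(tc_a, null), fold_onsets(tc_b, null))
        assert p < 0.0167 and t < 0

    def test_pure_noise_folds_all_absent_and_comparison_skipped(self):
        null = fake_null(sd=0.02, seed=11)
        tc = fake_timecourse(np.full(len(GRID), 0.25), noise=0.02, seed=12)
        with pytest.warns(UserWarning, match="no qualifying"):
            onsets = fold_onsets(tc, null)
        assert all(o is None for o in onsets)
        with pytest.warns(UserWarning, match="skipped"):
            t, p = compare_fold_onsets(onsets, [100.0] * 20)
        assert t is None and p is None


@pytest.fixture(scope="module")
def dataset():
    ep = make_noise_epochs(64, 4, 10, seed=20)
    labels = np.repeat([0, 1], 32)
    return LabeledDataset(ep, labels)


class TestPermutationNull:
    SPEC = DecoderSpec(n_folds=8)

    def test_shape_and_determinism(self, dataset):
        a = permutation_null(dataset, self.SPEC, n_perm=6, seed=21)
        b = permutation_null(dataset, self.SPEC, n_perm=6, seed=21)
        assert a.accuracies.shape == (6, 10)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_null_centered_at_chance(self, dataset):
        null = permutation_null(dataset, self.SPEC, n_perm=24, seed=22)
        se = null.accuracies.std() / np.sqrt(null.accuracies.size / 10)
        assert abs(null.accuracies.mean() - 0.5) < max(4 * se, 0.03)

    def test_too_few_permutations_rejected(self, dataset):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(dataset, self.SPEC, n_perm=1, seed=23)

    def test_held_out_null_runs_produce_no_onsets(self):
        """Leave-one-out calibration: a held-out shuffle run tested against
        the remaining ensemble almost never yields a sustained onset."""
        null = fake_null(n_perm=40, sd=0.02, seed=24)
        hits = 0
        for k in range(null.n_perm):
            rest = NullEnsemble(
                accuracies=np.delete(null.accuracies, k, axis=0),
                time_ms=null.time_ms, seeds=np.delete(null.seeds, k),
            )
            tc = fake_timecourse(null.accuracies[k])
            tr = significance_trace(tc, rest)
            if detect_onset(tr).onset_ms is not None:
                hits += 1
        assert hits == 0


class TestConditionContrasts:
    def test_identical_conditions_show_no_epochs(self):
        tc = fake_timecourse(np.full(len(GRID), 0.6), noise=0.03, seed=30)
        out = compare_conditions(tc, tc)
        assert not out.significant.any()
        assert out.epochs == [] and out.onset_ms is None

    def test_difference_restricted_to_injected_interval(self):
        base = np.full(len(GRID), 0.5)
        boosted = base + np.where((GRID >= 150.0) & (GRID <= 250.0), 0.3, 0.0)
        tc_a = fake_timecourse(boosted, noise=0.05, seed=31)
        tc_b = fake_timecourse(base, noise=0.05, seed=32)
        out = compare_conditions(tc_a, tc_b)
        assert len(out.epochs) == 1
        lo, hi = out.epochs[0]
        assert 130.0 <= lo <= 170.0 and 230.0 <= hi <= 270.0
        assert out.onset_ms == lo + 20.0

    def test_equal_conditions_rarely_produce_long_epochs(self):
        """Null simulation: equal fold-accuracy distributions give a >= 40 ms
        epoch at the Bonferroni alpha in at most 1 of 20 replicates."""
        n_bad = 0
        for rep in range(20):
            tc_a = fake_timecourse(np.full(len(GRID), 0.5), noise=0.05, seed=100 + rep)
            tc_b = fake_timecourse(np.full(len(GRID), 0.5), noise=0.05, seed=200 + rep)
            if compare_conditions(tc_a, tc_b).epochs:
                n_bad += 1
        assert n_bad <= 1

    def test_fold_onset_comparison_attached_when_nulls_given(self):
        null = fake_null(sd=0.02, seed=33)
        tc_a = fake_timecourse(np.where(GRID >= 100.0, 0.95, 0.25), noise=0.01, seed=34)
        tc_b = fake_timecourse(np.where(GRID >= 200.0, 0.95, 0.25), noise=0.01, seed=35)
        out = compare_conditions(tc_a, tc_b, null_a=null, null_b=null)
        assert out.onset_p is not None and out.onset_p < 0.0167

    def test_unequal_time_axes_rejected(self):
        tc_a = fake_timecourse(np.full(len(GRID), 0.5))
        tc_b = fake_timecourse(np.full(90, 0.5), time_ms=GRID[:90])
        with pytest.raises(ValueError, match="time axis"):
            compare_conditions(tc_a, tc_b)


class TestEndToEndOnsetRecovery:
    def test_amplitude_ladder_never_delays_onset(self):
        """Monotonicity: larger injected amplitude cannot move the recovered
        onset later (absent onsets count as +inf)."""
        n, ch, nb = 96, 6, 50
        base = make_noise_epochs(n, ch, nb, seed=40).data.astype(np.float32)
        labels = np.repeat([0, 1], 48)
        pattern = np.linspace(1.0, -1.0, ch).astype(np.float32)
        onsets = []
        spec = DecoderSpec(n_folds=8)
        for amp in (0.15, 0.4, 2.0):
            data = base.copy()
            for i, lab in enumerate(labels):
                sign = 1.0 if lab else -1.0
                data[i, :, 25:] += amp * sign * pattern[:, None]
            ep = make_noise_epochs(n, ch, nb, seed=40)
            ep.data = data
            ds = LabeledDataset(ep, labels)
            tc = run_balanced_decoding(ds, spec, seed=41)
            null = permutation_null(ds, spec, n_perm=20, seed=42)
            onset = detect_onset(significance_trace(tc, null)).onset_ms
            onsets.append(np.inf if onset is None else onset)
        assert onsets[-1] < np.inf
        assert all(a >= b for a, b in zip(onsets, onsets[1:]))
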