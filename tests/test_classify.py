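import math
from dataclasses import replace

import numpy as np
import pytest

import multiroi as mr
from multiroi.classify import ExperimentConfig, KernelConfig, RunMetrics, inner_tune


class TestRbfKernel:
    def test_identical_rows_give_one(self, rng):
        X = rng.normal(size=(5, 4))
        K = mr.rbf_kernel(X, X, gamma=0.7)
        assert np.allclose(np.diag(K), 1.0)

    def test_exp_minus_one_at_unit_distance(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[1.0, 0.0]])
        assert mr.rbf_kernel(a, b, gamma=1.0)[0, 0] == pytest.approx(math.exp(-1))

    def test_symmetric_psd(self, rng):
        X = rng.normal(size=(12, 6))
        K = mr.rbf_kernel(X, X, gamma=0.3)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            mr.rbf_kernel(X, X, gamma=0.0)
        with pytest.raises(ValueError):
            mr.rbf_kernel(X, rng.normal(size=(3, 5)), gamma=1.0)


class TestCombineKernels:
    def test_endpoints_exact(self, rng):
        X = rng.normal(size=(6, 3))
        K1 = mr.rbf_kernel(X, X, 0.5)
        K2 = mr.rbf_kernel(X, X, 2.0)
        assert np.array_equal(mr.combine_kernels(K1, K2, 1.0), K1)
        assert np.array_equal(mr.combine_kernels(K1, K2, 0.0), K2)

    def test_weighting_arithmetic(self):
        K1, K2 = np.array([[1.0]]), np.array([[0.0]])
        assert mr.combine_kernels(K1, K2, 0.65)[0, 0] == pytest.approx(0.65)

    def test_convex_combination_stays_psd(self, rng):
        X = rng.normal(size=(10, 4))
        K1 = mr.rbf_kernel(X, X, 0.2)
        K2 = mr.rbf_kernel(X[:, ::-1], X[:, ::-1], 1.5)
        for beta in (0.0, 0.3, 0.65, 1.0):
            K = mr.combine_kernels(K1, K2, beta)
            assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid(self, rng):
        K = np.eye(3)
        with pytest.raises(ValueError):
            mr.combine_kernels(K, K, 1.2)
        with pytest.raises(ValueError):
            mr.combine_kernels(K, np.eye(4), 0.5)


class TestRunMetrics:
    def test_worked_confusion_example(self):
        """tp=19, fn=1, tn=18, fp=2 reproduces all seven metrics by hand."""
        m = RunMetrics.from_confusion(19, 1, 18, 2, auc=0.97)
        assert m.sen == pytest.approx(0.95)
        assert m.spe == pytest.approx(0.90)
        assert m.acc == pytest.approx(0.925)
        assert m.bac == pytest.approx(0.925)
        assert m.youden == pytest.approx(0.85)
        assert m.f_score == pytest.approx(0.926829, abs=1e-6)

    def test_identities_on_random_confusions(self, rng):
        for _ in range(25):
            tp, fn, tn, fp = rng.integers(0, 30, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = RunMetrics.from_confusion(int(tp), int(fn), int(tn), int(fp), auc=0.5)
            assert m.acc == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            assert m.bac == pytest.approx((m.sen + m.spe) / 2)
            assert m.youden == pytest.approx(m.sen + m.spe - 1)

    def test_from_scores_thresholds_at_zero(self):
        y = np.array([1, 1, -1, -1])
        m = RunMetrics.from_scores(y, np.array([2.0, -0.5, -1.0, 0.5]))
        assert m.confusion == (1, 1, 1, 1)
        assert m.auc == pytest.approx(0.75)


class TestPairedAccuracyTest:
    def test_worked_example(self):
        """Differences (0.1, 0.2, 0.15, 0.05): t = 3.873 on 3 df, p ~ 0.0305."""
        b = np.array([0.5, 0.5, 0.5, 0.5])
        a = b + np.array([0.1, 0.2, 0.15, 0.05])
        t, p = mr.paired_accuracy_test(a, b)
        # oracle: mean d = 0.125, sd = 0.064550, se = 0.032275
        assert t == pytest.approx(0.125 / (np.std(a - b, ddof=1) / 2), rel=1e-12)
        assert t == pytest.approx(3.8730, abs=1e-4)
        assert p == pytest.approx(0.030466, abs=1e-5)

    def test_identical_vectors_degenerate(self):
        t, p = mr.paired_accuracy_test([0.6, 0.7], [0.6, 0.7])
        assert math.isnan(t) and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p = mr.paired_accuracy_test([0.7, 0.8], [0.6, 0.7])
        assert t == math.inf and p == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(10), rng.random(10)
        t1, p1 = mr.paired_accuracy_test(a, b)
        t2, p2 = mr.paired_accuracy_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestInnerTune:
    def _grids(self, X, y, gammas):
        return {"roi": [(g, mr.rbf_kernel(X, X, g)) for g in gammas]}

    def test_single_grid_point_returned(self, rng):
        y = np.array([1, 1, -1, -1, 1, -1])
        X = rng.normal(size=(6, 3))
        cfg = KernelConfig(beta=1.0, gamma_grid=(1.0,), C_grid=(2.0,))
        got = inner_tune(self._grids(X, y, [0.5]), y, 1.0, cfg, seed=0)
        assert got == (0.5, None, 2.0)

    def test_separable_fixture_prefers_separating_gamma(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 8 + [-1] * 8)
        X = rng.normal(size=(16, 2)) + 5.0 * y[:, None]
        cfg = KernelConfig(beta=1.0, gamma_grid=(1.0,), C_grid=(1.0,))
        # gamma so large every off-diagonal entry is ~0 (degenerate) vs sane
        grids = self._grids(X, y, [1e6, 0.05])
        g, _, _ = inner_tune(grids, y, 1.0, cfg, seed=0)
        assert g == 0.05

    def test_deterministic(self, rng):
        y = np.array([1, -1] * 6)
        X = rng.normal(size=(12, 4))
        cfg = KernelConfig(beta=1.0)
        grids = self._grids(X, y, [0.1, 1.0, 10.0])
        assert inner_tune(grids, y, 1.0, cfg, 5) == inner_tune(grids, y, 1.0, cfg, 5)


class TestEvaluateSplit:
    def test_separable_groups_classified_perfectly(self, separable_cohort):
        feats = mr.extract_features(separable_cohort)
        labels = feats["gmv"].labels
        train = np.concatenate([np.flatnonzero(labels == 1)[:4], np.flatnonzero(labels == -1)[:4]])
        test = np.setdiff1d(np.arange(len(labels)), train)
        m, sel = mr.evaluate_split(feats, train, test, ExperimentConfig(seed=0), inner_seed=0)
        assert m.acc == 1.0
        assert m.auc == 1.0
        assert len(sel) > 0

    def test_leakage_guard(self, small_features):
        cfg = ExperimentConfig(seed=0)
        with pytest.raises(ValueError, match="leakage"):
            mr.evaluate_split(small_features, [0, 1, 2, 6, 7], [2, 8, 9], cfg)

    def test_single_class_half_rejected(self, small_features):
        cfg = ExperimentConfig(seed=0)
        labels = small_features["gmv"].labels
        high = list(np.flatnonzero(labels == 1))
        low = list(np.flatnonzero(labels == -1))
        with pytest.raises(ValueError, match="both classes"):
            mr.evaluate_split(small_features, high, low, cfg)


class TestRepeatedNestedCV:
    def test_run_bookkeeping_and_reproducibility(self, small_features):
        cfg = ExperimentConfig(seed=9)
        r1 = mr.repeated_nested_cv(small_features, cfg, n_repeats=1)
        assert r1.n_runs == 2
        r2 = mr.repeated_nested_cv(small_features, cfg, n_repeats=1)
        assert [m.as_dict() for m in r1.per_run] == [m.as_dict() for m in r2.per_run]
        assert r1.selected_per_run == r2.selected_per_run

    def test_selection_frequencies_bounded(self, small_features):
        res = mr.repeated_nested_cv(small_features, ExperimentConfig(seed=2), n_repeats=2)
        assert res.n_runs == 4
        assert all(c <= res.n_runs for c in res.selection_counts.values())

    def test_metric_identities_hold_per_run(self, small_features):
        res = mr.repeated_nested_cv(small_features, ExperimentConfig(seed=3), n_repeats=1)
        for m in res.per_run:
            tp, fn, tn, fp = m.confusion
            assert m.acc == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            assert m.bac == pytest.approx((m.sen + m.spe) / 2)
            assert m.youden == pytest.approx(m.sen + m.spe - 1)

    def test_beta_endpoints_reproduce_single_kernel_runs(self, separable_cohort):
        feats = mr.extract_features(separable_cohort)
        base = ExperimentConfig(seed=4)
        multilevel_b1 = replace(base, kernel=replace(base.kernel, beta=1.0))
        roi_only = replace(
            base, use_similarity=False, kernel=replace(base.kernel, beta=1.0)
        )
        ra = mr.repeated_nested_cv(feats, multilevel_b1, n_repeats=2)
        rb = mr.repeated_nested_cv(feats, roi_only, n_repeats=2)
        assert [m.as_dict() for m in ra.per_run] == [m.as_dict() for m in rb.per_run]

        multilevel_b0 = replace(base, kernel=replace(base.kernel, beta=0.0))
        sim_only = base.single_type("similarity")
        rc = mr.repeated_nested_cv(feats, multilevel_b0, n_repeats=2)
        rd = mr.repeated_nested_cv(feats, sim_only, n_repeats=2)
        assert [m.as_dict() for m in rc.per_run] == [m.as_dict() for m in rd.per_run]

    def test_too_small_cohort_rejected(self):
        cohort, _ = mr.generate_cohort(mr.EffectSpec(n_high=2, n_low=2, seed=0))
        feats = mr.extract_features(cohort)
        with pytest.raises(ValueError, match="too small"):
            mr.repeated_nested_cv(feats, ExperimentConfig(seed=0), n_repeats=1)

    def test_monotone_signal_response(self):
        """Stronger planted effects never reduce mean accuracy (matched seeds)."""
        accs = []
        for d in (0.0, 1.5, 3.0):
            spec = mr.EffectSpec(
                roi_effects=[(5, "gmv", d), (12, "wmv", d), (23, "thk", d), (40, "area", d)],
                n_high=16, n_low=16, seed=21,
            )
            cohort, _ = mr.generate_cohort(spec)
            feats = mr.extract_features(cohort)
            res = mr.repeated_nested_cv(feats, ExperimentConfig(seed=6), n_repeats=2)
            accs.append(res.summary()["acc"][0])
        assert accs[0] <= accs[1] + 0.1  # non-strict, small-sample tolerance
        assert accs[1] <= accs[2] + 0.1
        assert accs[2] >= 0.75  # strong effects are clearly detected
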