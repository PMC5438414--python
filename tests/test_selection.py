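import math

import numpy as np
import pytest
from sklearn.svm import SVC

import multiroi as mr
from multiroi.selection import SelectionConfig, _discretize, _mutual_information


def _welch_oracle(a, b):
    """Hand-rolled Welch statistic with Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestTtestFilter:
    def test_welch_worked_example(self):
        """A=(1..5), B=(3..7): Welch t = -2.0 on 8 df, p ~ 0.081 -> removed."""
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([3.0, 4, 5, 6, 7])
        t, df = _welch_oracle(a, b)
        assert t == pytest.approx(-2.0)
        assert df == pytest.approx(8.0)
        X = np.concatenate([a, b])[:, None]
        y = np.array([1] * 5 + [-1] * 5)
        kept, p = mr.ttest_filter(X, 0.05, y=y)
        assert p[0] == pytest.approx(0.080517, abs=1e-5)
        assert kept == []

    def test_identical_groups_removed_separated_kept(self, rng):
        n = 8
        same = rng.normal(0, 1, n)  # identical values in both groups -> p ~ 1
        apart = np.concatenate([rng.normal(0, 0.1, n), 10 + rng.normal(0, 0.1, n)])
        constant = np.zeros(2 * n)
        X = np.column_stack([np.concatenate([same, same]), apart, constant])
        y = np.array([1] * n + [-1] * n)
        with pytest.warns(UserWarning, match="zero-variance"):
            kept, p = mr.ttest_filter(X, 0.05, y=y)
        assert kept == [1]
        assert p[0] > 0.99
        assert p[1] < 1e-6
        assert 2 not in p  # constant feature dropped before testing

    def test_null_features_kept_at_alpha_rate(self, rng):
        X = rng.normal(size=(40, 600))
        y = np.array([1] * 20 + [-1] * 20)
        kept, _ = mr.ttest_filter(X, 0.05, y=y)
        frac = len(kept) / 600
        assert 0.02 <= frac <= 0.09  # ~binomial(600, 0.05) band

    def test_single_class_error(self, rng):
        with pytest.raises(ValueError):
            mr.ttest_filter(rng.normal(size=(6, 3)), 0.05, y=np.ones(6))


def _mrmr_oracle(X, y, k, scheme):
    """Exhaustive greedy re-derivation, independent bookkeeping."""
    disc = _discretize(X)
    ycode = (y == y.max()).astype(np.int64)
    n = X.shape[1]
    rel = [_mutual_information(disc[:, j], ycode) for j in range(n)]
    chosen = []
    while len(chosen) < min(k, n):
        best_j, best_score = None, -np.inf
        for j in range(n):
            if j in chosen:
                continue
            if not chosen:
                score = rel[j]
            else:
                red = np.mean([_mutual_information(disc[:, j], disc[:, s]) for s in chosen])
                score = rel[j] - red if scheme == "difference" else rel[j] / (red + 1e-12)
            if score > best_score:
                best_j, best_score = j, score
        chosen.append(best_j)
    return chosen


class TestMrmr:
    def test_label_feature_ranked_first(self, rng):
        y = np.array([1] * 10 + [-1] * 10)
        X = rng.normal(size=(20, 5))
        # +/-10 with two mid-range values: the mean +/- SD cut points fall
        # inside, so the discretized feature reproduces the label exactly
        X[:, 3] = y * 10.0
        X[0, 3] = X[10, 3] = 0.0
        order = mr.mrmr_select(X, y, k=5)
        assert order[0] == 3

    @pytest.mark.parametrize("scheme", ["difference", "quotient"])
    def test_greedy_matches_exhaustive_oracle(self, scheme):
        rng = np.random.default_rng(123)
        for trial in range(50):
            n_feat = int(rng.integers(2, 9))
            X = rng.normal(size=(20, n_feat))
            y = np.where(rng.random(20) < 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                y[0] = -y[0]
            X[:, 0] += y  # give at least one feature real relevance
            k = int(rng.integers(1, n_feat + 1))
            assert mr.mrmr_select(X, y, k=k, scheme=scheme) == _mrmr_oracle(X, y, k, scheme)

    def test_duplicate_feature_penalized(self, rng):
        """A copy of the best feature is not picked straight after it."""
        y = np.array([1] * 15 + [-1] * 15)
        informative = y + rng.normal(0, 0.3, 30)
        other = y * 0.5 + rng.normal(0, 1.0, 30)  # weaker but positive relevance
        X = np.column_stack([informative, informative.copy(), other])
        order = mr.mrmr_select(X, y, k=3)
        assert order[0] == 0
        assert order[1] == 2  # redundancy pushes the clone behind `other`

    def test_k_validation(self, rng):
        with pytest.raises(ValueError):
            mr.mrmr_select(rng.normal(size=(10, 3)), np.array([1, -1] * 5), k=0)


def _rfe_oracle_order(X, y, C=1.0):
    """One-at-a-time elimination, retraining each round (independent loop)."""
    active = list(range(X.shape[1]))
    eliminated = []
    while len(active) > 1:
        clf = SVC(kernel="linear", C=C).fit(X[:, active], y)
        w2 = np.ravel(clf.coef_) ** 2
        worst = active[int(np.argmin(w2))]
        eliminated.append(worst)
        active.remove(worst)
    return active + eliminated[::-1]  # best first


class TestSvmRfe:
    def test_rank_matches_one_at_a_time_oracle(self, rng):
        y = np.array([1] * 10 + [-1] * 10)
        X = rng.normal(size=(20, 6))
        X[:, 1] += 1.5 * y
        X[:, 4] += 0.8 * y
        cfg = SelectionConfig(rfe_drop_fraction=0.0)
        _, rank = mr.svm_rfe(X, y, config=cfg, inner_cv_seed=0)
        assert rank == _rfe_oracle_order(X, y)

    def test_two_features_bookkeeping(self, rng):
        y = np.array([1] * 6 + [-1] * 6)
        X = rng.normal(size=(12, 2))
        kept, rank = mr.svm_rfe(X, y)
        assert sorted(rank) == [0, 1]
        assert set(kept) <= {0, 1}

    def test_separating_feature_survives(self):
        survived = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.array([1] * 12 + [-1] * 12)
            X = r.normal(size=(24, 10))
            X[:, 7] = y * 3 + r.normal(0, 0.1, 24)
            kept, _ = mr.svm_rfe(X, y, inner_cv_seed=seed)
            survived += 7 in kept
        assert survived >= 19

    def test_degenerate_input_error(self):
        X = np.ones((8, 3))
        y = np.array([1, -1] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            mr.svm_rfe(X, y)


class TestHybrid:
    def test_stage_counts_non_increasing(self, small_features):
        fm = small_features["gmv"]
        res = mr.hybrid_select(fm, seed=0)
        n_in, n_t, n_m, n_k = res.stage_counts
        assert n_in >= n_t >= n_m >= n_k >= 1
        assert set(res.kept_ids) <= set(res.stage_trace["mrmr_order"])
        assert set(res.stage_trace["mrmr_order"]) <= {
            f for f, p in res.stage_trace["pvalues"].items() if p < 0.05
        } or res.stage_trace["ttest_fallback"]

    def test_planted_features_dominate_ranking(self):
        """Strong planted features occupy the head of the elimination rank
        and everything the cascade keeps is planted; the subset-size rule
        prefers the smallest subset whose inner-CV accuracy is maximal, so
        the kept set may be a subset of the planted features."""
        rank_hits, head_hits, pure = 0, 0, 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.array([1] * 20 + [-1] * 20)
            X = r.normal(size=(40, 30))
            planted = {2, 7, 11, 19, 28}
            for j in planted:
                X[:, j] += 1.5 * y
            res = mr.hybrid_select(X, y, seed=seed)
            rank = res.stage_trace["rfe_rank"]
            rank_hits += len(set(rank[:5]) & planted) >= 4
            head_hits += planted <= set(rank[:7])
            pure += set(res.kept_ids) <= planted
        assert rank_hits >= 9
        assert head_hits >= 9
        assert pure >= 9

    def test_fallback_when_nothing_passes(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([1] * 6 + [-1] * 6)
        res = mr.hybrid_select(X, y, config=SelectionConfig(alpha=1e-12), seed=0)
        assert res.stage_trace["ttest_fallback"]
        assert len(res.kept_ids) == 1

    def test_selection_uses_training_labels_only(self, small_features):
        """Interface check: selection sees one matrix and its labels; no
        held-out rows are available to it."""
        fm = small_features["thickness"]
        train = fm.subset_rows(np.arange(0, 8))
        res = mr.hybrid_select(train, seed=1)
        assert all(fid in fm.feature_ids for fid in res.kept_ids)
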