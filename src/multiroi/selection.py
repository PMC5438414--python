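"""Hybrid feature-selection cascade: t-test filter, mRMR re-ranking, SVM-RFE.

The cascade runs three stages on training data only:

1. **t-test filter** — per-feature two-sample Welch t-test between groups;
   keep features with p below a threshold (default 0.05).
2. **mRMR** — greedy forward selection maximizing mutual-information
   relevance to the label minus (or divided by) mean redundancy with the
   already-selected set, on features discretized into 3 bins at mean +/- SD.
3. **SVM-RFE** — backward elimination with a linear soft-margin SVM,
   discarding the smallest-squared-weight features each round; the final
   subset size is picked from a candidate grid by stratified 2-fold
   cross-validation accuracy on the training rows (ties favor the smaller
   subset).

Every ranking breaks ties by input feature order, which is canonical ROI
index order, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "ttest_filter",
    "mrmr_select",
    "svm_rfe",
    "hybrid_select",
]

DEFAULT_SUBSET_GRID = (1, 2, 3, 5, 8, 12, 16, 24, 32, 48)


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable knobs of the cascade."""

    alpha: float = 0.05
    mrmr_k: int = 50
    mrmr_scheme: str = "difference"  # or "quotient"
    rfe_drop_fraction: float = 0.1  # 0 -> strict one-at-a-time elimination
    rfe_subset_grid: tuple[int, ...] = DEFAULT_SUBSET_GRID
    rfe_C: float = 1.0
    rfe_cv_repeats: int = 5  # repeated 2-fold splits averaged for the size choice

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mrmr_k < 1:
            raise ValueError("mrmr_k must be >= 1")
        if self.mrmr_scheme not in ("difference", "quotient"):
            raise ValueError("mrmr_scheme must be 'difference' or 'quotient'")
        if not 0 <= self.rfe_drop_fraction < 1:
            raise ValueError("rfe_drop_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SelectionResult:
    """Surviving features and a per-stage audit trail."""

    kept_ids: tuple
    stage_trace: dict = field(default_factory=dict)
    config_used: SelectionConfig = field(default_factory=SelectionConfig)

    @property
    def stage_counts(self) -> tuple[int, int, int, int]:
        t = self.stage_trace
        return (t["n_input"], t["n_after_ttest"], t["n_after_mrmr"], len(self.kept_ids))


def _split_xy(X, y):
    """Accept a FeatureMatrix (labels built in) or a plain array + labels."""
    if isinstance(X, FeatureMatrix):
        return X.values, (X.labels if y is None else np.asarray(y)), list(X.feature_ids)
    if y is None:
        raise ValueError("labels required when X is a plain array")
    X = np.asarray(X, dtype=float)
    return X, np.asarray(y), list(range(X.shape[1]))


def ttest_filter(X, alpha: float = 0.05, y=None):
    """Welch two-sample t-test per feature; keep features with p < alpha.

    Returns ``(surviving_ids, pvalues)`` where ``pvalues`` maps every tested
    feature id to its p-value.  Zero-variance features are dropped (with a
    warning) before testing.
    """
    values, labels, ids = _split_xy(X, y)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ttest_filter requires both classes present")
    a = values[labels == classes.max()]
    b = values[labels == classes.min()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ttest_filter requires >= 2 subjects per class")

    variance = values.var(axis=0)
    degenerate = variance == 0
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} zero-variance feature(s) before t-test",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    pvalues = {ids[k]: float(p[k]) for k in range(len(ids)) if not degenerate[k]}
    surviving = [ids[k] for k in range(len(ids)) if not degenerate[k] and p[k] < alpha]
    return surviving, pvalues


def _discretize(values: np.ndarray) -> np.ndarray:
    """3-level discretization at mean +/- SD, column-wise (Ding & Peng)."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    out = np.ones(values.shape, dtype=np.int64)
    out[values < mu - sd] = 0
    out[values > mu + sd] = 2
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small-integer arrays via the contingency table."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_select(X, y=None, k: int = 50, scheme: str = "difference"):
    """Greedy minimum-redundancy / maximum-relevance ranking.

    Relevance is the mutual information between a discretized feature and
    the class label; redundancy is the mean MI with the features already
    selected.  The first pick maximizes relevance alone; later picks
    maximize ``relevance - redundancy`` (difference scheme) or
    ``relevance / redundancy`` (quotient scheme).  Returns the first
    ``min(k, n_candidates)`` feature ids in selection order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values, labels, ids = _split_xy(X, y)
    n_feat = values.shape[1]
    if n_feat == 0:
        return []
    disc = _discretize(values)
    ycode = (labels == np.unique(labels).max()).astype(np.int64)

    relevance = np.array(
        [_mutual_information(disc[:, j], ycode) for j in range(n_feat)]
    )
    selected: list[int] = []
    remaining = list(range(n_feat))
    redundancy_sum = np.zeros(n_feat)
    while remaining and len(selected) < min(k, n_feat):
        if not selected:
            scores = relevance[remaining]
        else:
            last = selected[-1]
            for j in remaining:
                redundancy_sum[j] += _mutual_information(disc[:, j], disc[:, last])
            red = redundancy_sum[np.array(remaining)] / len(selected)
            if scheme == "difference":
                scores = relevance[remaining] - red
            else:
                scores = relevance[remaining] / (red + 1e-12)
        pick = remaining[int(np.argmax(scores))]  # first max -> input-order ties
        selected.append(pick)
        remaining.remove(pick)
    return [ids[j] for j in selected]


def _linear_svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C)


def svm_rfe(X, y=None, config: SelectionConfig | None = None, inner_cv_seed: int = 0):
    """SVM-recursive feature elimination with inner-CV subset-size choice.

    Repeatedly fits a linear soft-margin SVM, ranks features by squared
    weight and removes the lowest ``rfe_drop_fraction`` (at least one) per
    round until one feature remains.  The survivor-first rank order and the
    subset size chosen by stratified 2-fold CV accuracy are returned as
    ``(kept_ids, rank_order)``.
    """
    config = config or SelectionConfig()
    values, labels, ids = _split_xy(X, y)
    n_feat = values.shape[1]
    if n_feat < 1:
        raise ValueError("svm_rfe requires at least one feature")
    if len(np.unique(labels)) < 2:
        raise ValueError("svm_rfe requires both classes present")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate input: all rows identical")
    if n_feat == 1:
        return list(ids), list(ids)

    active = list(range(n_feat))
    eliminated: list[int] = []
    while len(active) > 1:
        clf = _linear_svm(config.rfe_C).fit(values[:, active], labels)
        w2 = np.ravel(clf.coef_) ** 2
        n_drop = max(1, int(config.rfe_drop_fraction * len(active)))
        n_drop = min(n_drop, len(active) - 1)
        # smallest squared weights go first; stable sort -> input-order ties
        order = np.argsort(w2, kind="stable")
        drop_local = list(order[:n_drop])
        for t in drop_local:
            eliminated.append(active[t])
        active = [a for t, a in enumerate(active) if t not in set(drop_local)]
    rank = active + eliminated[::-1]  # best first

    grid = sorted({s for s in config.rfe_subset_grid if 1 <= s <= n_feat} | {n_feat})
    # averaged repeated stratified 2-fold accuracy: one noisy split would
    # often tie or spuriously favor tiny subsets
    folds = []
    for rep in range(config.rfe_cv_repeats):
        cv = StratifiedKFold(n_splits=2, shuffle=True,
                             random_state=(inner_cv_seed + rep) % (2**31))
        folds.extend(cv.split(values, labels))
    best_size, best_acc = grid[0], -1.0
    for size in grid:
        cols = rank[:size]
        accs = []
        for tr, va in folds:
            clf = _linear_svm(config.rfe_C).fit(values[np.ix_(tr, cols)], labels[tr])
            accs.append(np.mean(clf.predict(values[np.ix_(va, cols)]) == labels[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict -> ties keep the smaller subset
            best_acc, best_size = acc, size
    kept = rank[:best_size]
    return [ids[j] for j in kept], [ids[j] for j in rank]


def hybrid_select(
    X, y=None, config: SelectionConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Run the full t-test -> mRMR -> SVM-RFE cascade on training data.

    If the t-test stage keeps nothing, the single smallest-p feature is
    carried forward (recorded in ``stage_trace['ttest_fallback']``).
    """
    config = config or SelectionConfig()
    values, labels, ids = _split_xy(X, y)
    trace: dict = {"n_input": len(ids)}

    surviving, pvalues = ttest_filter(values, config.alpha, y=labels)
    surviving_ids = [ids[j] for j in surviving]
    trace["pvalues"] = {ids[j]: pv for j, pv in pvalues.items()}
    trace["ttest_fallback"] = False
    if not surviving_ids:
        best = min(pvalues, key=lambda j: (pvalues[j], j))
        surviving = [best]
        surviving_ids = [ids[best]]
        trace["ttest_fallback"] = True
    trace["n_after_ttest"] = len(surviving_ids)

    sub = values[:, surviving]
    mrmr_local = mrmr_select(sub, labels, k=config.mrmr_k, scheme=config.mrmr_scheme)
    mrmr_cols = [surviving[j] for j in mrmr_local]
    trace["mrmr_order"] = [ids[c] for c in mrmr_cols]
    trace["n_after_mrmr"] = len(mrmr_cols)

    if len(mrmr_cols) == 1:
        kept_cols, rank = mrmr_cols, mrmr_cols
    else:
        kept_local, rank_local = svm_rfe(
            values[:, mrmr_cols], labels, config=config, inner_cv_seed=seed
        )
        kept_cols = [mrmr_cols[j] for j in kept_local]
        rank = [mrmr_cols[j] for j in rank_local]
    trace["rfe_rank"] = [ids[c] for c in rank]
    trace["n_kept"] = len(kept_cols)

    return SelectionResult(
        kept_ids=tuple(ids[c] for c in kept_cols),
        stage_trace=trace,
        config_used=config,
    )
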