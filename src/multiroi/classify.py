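"""Multi-kernel RBF SVM with repeated nested cross-validation.

Two Gaussian kernels are built on held-apart feature families — the
concatenated per-type ROI features and the thickness-similarity features —
and fused entrywise as ``beta * K_roi + (1 - beta) * K_sim`` with a
weighting factor ``beta`` in [0, 1].  Hyperparameters (both RBF widths and
the soft-margin C) are tuned by a stratified 2-fold inner loop on the
training half only; the outer loop is a class-stratified random half-split,
evaluated in both directions (train/test swapped) and repeated, yielding
``2 * n_repeats`` runs whose metrics and selected-feature frequencies are
aggregated.

Feature selection (the t-test/mRMR/SVM-RFE cascade) runs inside every outer
training half, so held-out subjects never influence which features — or
which hyperparameters — are used to score them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import ROI_FEATURE_TYPES, FeatureMatrix
from .selection import SelectionConfig, hybrid_select

__all__ = [
    "KernelConfig",
    "ExperimentConfig",
    "RunMetrics",
    "EvaluationResult",
    "rbf_kernel",
    "combine_kernels",
    "inner_tune",
    "evaluate_split",
    "repeated_nested_cv",
    "paired_accuracy_test",
]

_DEF_GAMMA = tuple(2.0**k for k in (-5, -3, -1, 1, 3, 5))
_DEF_C = tuple(2.0**k for k in (-3, -1, 1, 3, 5))


@dataclass(frozen=True)
class KernelConfig:
    """Kernel fusion weight and hyperparameter grids.

    ``gamma_grid`` entries are multipliers of a data-driven scale
    (1 / median pairwise squared training distance per feature block).
    """

    beta: float = 0.65
    gamma_grid: tuple[float, ...] = _DEF_GAMMA
    C_grid: tuple[float, ...] = _DEF_C
    inner_folds: int = 2

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not self.gamma_grid or not self.C_grid:
            raise ValueError("gamma/C grids must be non-empty")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one evaluation needs: feature families, selection, kernels."""

    roi_types: tuple[str, ...] = ROI_FEATURE_TYPES
    use_similarity: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    seed: int = 0

    def single_type(self, feature_type: str) -> "ExperimentConfig":
        """Config for a single-feature-type run (one kernel, beta pinned)."""
        if feature_type == "similarity":
            return replace(self, roi_types=(), use_similarity=True,
                           kernel=replace(self.kernel, beta=0.0))
        if feature_type == "vol_union":
            types: tuple[str, ...] = ("gmv", "wmv", "csfv")
        else:
            types = (feature_type,)
        return replace(self, roi_types=types, use_similarity=False,
                       kernel=replace(self.kernel, beta=1.0))


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix: entry (a, b) = exp(-gamma * ||x_a - x_b||^2)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    d2 = _sq_dists(A, B)
    return np.exp(-gamma * d2)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d2 = (
        (A**2).sum(axis=1)[:, None]
        + (B**2).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def combine_kernels(K_roi: np.ndarray, K_sim: np.ndarray, beta: float) -> np.ndarray:
    """Convex combination ``beta * K_roi + (1 - beta) * K_sim``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    K_roi = np.asarray(K_roi, dtype=float)
    K_sim = np.asarray(K_sim, dtype=float)
    if K_roi.shape != K_sim.shape:
        raise ValueError(f"kernel shape mismatch: {K_roi.shape} vs {K_sim.shape}")
    return beta * K_roi + (1.0 - beta) * K_sim


@dataclass(frozen=True)
class RunMetrics:
    """Metrics of one outer evaluation (positive class = high group)."""

    acc: float
    sen: float
    spe: float
    auc: float
    f_score: float
    youden: float
    bac: float
    confusion: tuple[int, int, int, int]  # tp, fn, tn, fp

    @classmethod
    def from_confusion(cls, tp: int, fn: int, tn: int, fp: int, auc: float) -> "RunMetrics":
        pos, neg = tp + fn, tn + fp
        sen = tp / pos if pos else 0.0
        spe = tn / neg if neg else 0.0
        acc = (tp + tn) / (pos + neg)
        precision = tp / (tp + fp) if tp + fp else 0.0
        f = (
            2 * precision * sen / (precision + sen)
            if precision + sen > 0
            else 0.0
        )
        return cls(
            acc=acc, sen=sen, spe=spe, auc=auc, f_score=f,
            youden=sen + spe - 1.0, bac=(sen + spe) / 2.0,
            confusion=(tp, fn, tn, fp),
        )

    @classmethod
    def from_scores(cls, y_true: np.ndarray, decision: np.ndarray) -> "RunMetrics":
        y_true = np.asarray(y_true)
        pred = np.where(np.asarray(decision) >= 0, 1, -1)
        tp = int(np.sum((y_true == 1) & (pred == 1)))
        fn = int(np.sum((y_true == 1) & (pred == -1)))
        tn = int(np.sum((y_true == -1) & (pred == -1)))
        fp = int(np.sum((y_true == -1) & (pred == 1)))
        auc = float(roc_auc_score((y_true == 1).astype(int), decision))
        return cls.from_confusion(tp, fn, tn, fp, auc)

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "sen": self.sen, "spe": self.spe, "auc": self.auc,
            "f_score": self.f_score, "youden": self.youden, "bac": self.bac,
            "tp": self.confusion[0], "fn": self.confusion[1],
            "tn": self.confusion[2], "fp": self.confusion[3],
        }


METRIC_NAMES = ("acc", "sen", "spe", "auc", "f_score", "youden", "bac")


@dataclass(frozen=True)
class EvaluationResult:
    """All runs of one repeated nested-CV experiment."""

    per_run: tuple[RunMetrics, ...]
    selected_per_run: tuple[tuple, ...]
    config: ExperimentConfig
    n_repeats: int

    @property
    def selection_counts(self) -> Counter:
        c: Counter = Counter()
        for sel in self.selected_per_run:
            c.update(set(sel))
        return c

    @property
    def n_runs(self) -> int:
        return len(self.per_run)

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.per_run])

    def summary(self) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, SD over runs)."""
        return {
            m: (float(self.metric(m).mean()), float(self.metric(m).std(ddof=1)))
            for m in METRIC_NAMES
        }


def _check_features(features: dict[str, FeatureMatrix]) -> np.ndarray:
    mats = list(features.values())
    if not mats:
        raise ValueError("no feature matrices given")
    ref = mats[0]
    for fm in mats[1:]:
        if fm.subject_ids != ref.subject_ids or not np.array_equal(fm.labels, ref.labels):
            raise ValueError("feature matrices disagree on subjects or labels")
    return ref.labels


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _select_block(features, types, y_train, train_idx, test_idx, sel_config, seed):
    """Per-type selection on training rows; returns fused standardized block."""
    train_parts, test_parts, kept_ids = [], [], []
    for ft in types:
        fm = features[ft]
        tr, te = _standardize(fm.values[train_idx], fm.values[test_idx])
        res = hybrid_select(tr, y_train, config=sel_config, seed=seed)
        cols = list(res.kept_ids)  # local column indices
        train_parts.append(tr[:, cols])
        test_parts.append(te[:, cols])
        kept_ids.extend(fm.feature_ids[c] for c in cols)
    return np.hstack(train_parts), np.hstack(test_parts), kept_ids


def _gamma_candidates(train_block: np.ndarray, grid) -> list[float]:
    d2 = _sq_dists(train_block, train_block)
    off = d2[~np.eye(len(d2), dtype=bool)]
    scale = float(np.median(off))
    if scale <= 0:
        scale = float(train_block.shape[1]) or 1.0
    return [g / scale for g in grid]


def inner_tune(K_grids: dict, y_train: np.ndarray, beta: float, config: KernelConfig, seed: int):
    """Stratified inner-CV grid search over (gamma_roi, gamma_sim, C).

    ``K_grids`` maps block name ('roi', 'sim') to a list of
    (gamma, train-kernel) pairs.  Returns the winning
    ``(gamma_roi, gamma_sim, C)`` with unused slots ``None``; ties go to the
    smallest C, then the smallest gammas (enumeration order).
    """
    roi_opts = K_grids.get("roi") or [(None, None)]
    sim_opts = K_grids.get("sim") or [(None, None)]
    cv = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(np.zeros(len(y_train)), y_train))

    best, best_acc = None, -1.0
    for C in sorted(config.C_grid):
        for g_roi, K_roi in roi_opts:
            for g_sim, K_sim in sim_opts:
                K = _fuse(K_roi, K_sim, beta)
                accs = []
                for tr, va in folds:
                    clf = SVC(kernel="precomputed", C=C)
                    clf.fit(K[np.ix_(tr, tr)], y_train[tr])
                    pred = clf.predict(K[np.ix_(va, tr)])
                    accs.append(np.mean(pred == y_train[va]))
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best_acc, best = acc, (g_roi, g_sim, C)
    return best


def _fuse(K_roi, K_sim, beta):
    if K_roi is None:
        return K_sim
    if K_sim is None:
        return K_roi
    return combine_kernels(K_roi, K_sim, beta)


def evaluate_split(
    features: dict[str, FeatureMatrix],
    train_idx,
    test_idx,
    config: ExperimentConfig,
    inner_seed: int = 0,
):
    """Select, tune, train on the training half; score the held-out half.

    Returns ``(RunMetrics, selected_feature_ids)``.  Selection and tuning
    see only ``train_idx`` rows; any overlap with ``test_idx`` is an error.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("train and test index sets must be non-empty")
    if set(train_idx) & set(test_idx):
        raise ValueError("leakage: train and test indices overlap")
    labels = _check_features(features)
    y_train, y_test = labels[train_idx], labels[test_idx]
    for name, y in (("train", y_train), ("test", y_test)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} half must contain both classes")

    beta = config.kernel.beta
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    kept: list = []
    if config.roi_types and beta > 0.0:
        tr, te, ids = _select_block(
            features, config.roi_types, y_train, train_idx, test_idx,
            config.selection, inner_seed,
        )
        blocks["roi"] = (tr, te)
        kept.extend(ids)
    if config.use_similarity and beta < 1.0:
        tr, te, ids = _select_block(
            features, ("similarity",), y_train, train_idx, test_idx,
            config.selection, inner_seed,
        )
        blocks["sim"] = (tr, te)
        kept.extend(ids)
    if not blocks:
        raise ValueError("configuration leaves no active feature block")

    K_grids = {
        name: [
            (g, rbf_kernel(tr, tr, g))
            for g in _gamma_candidates(tr, config.kernel.gamma_grid)
        ]
        for name, (tr, te) in blocks.items()
    }
    g_roi, g_sim, C = inner_tune(K_grids, y_train, beta, config.kernel, inner_seed)

    def block_kernels(name, gamma):
        tr, te = blocks[name]
        return rbf_kernel(tr, tr, gamma), rbf_kernel(te, tr, gamma)

    Kr_tr = Kr_te = Ks_tr = Ks_te = None
    if "roi" in blocks:
        Kr_tr, Kr_te = block_kernels("roi", g_roi)
    if "sim" in blocks:
        Ks_tr, Ks_te = block_kernels("sim", g_sim)
    K_train = _fuse(Kr_tr, Ks_tr, beta)
    K_cross = _fuse(Kr_te, Ks_te, beta)

    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K_train, y_train)
    decision = clf.decision_function(K_cross)
    return RunMetrics.from_scores(y_test, decision), tuple(kept)


def _half_split(labels: np.ndarray, rng: np.random.Generator, flip: bool):
    """Class-stratified random half-split; ``flip`` alternates where the odd
    subject of an odd-sized class lands across repeats."""
    part_a: list[int] = []
    part_b: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        half = len(perm) // 2
        if len(perm) % 2 and flip:
            half += 1
        part_a.extend(perm[:half])
        part_b.extend(perm[half:])
    return np.sort(part_a), np.sort(part_b)


def repeated_nested_cv(
    features: dict[str, FeatureMatrix],
    config: ExperimentConfig,
    n_repeats: int = 100,
) -> EvaluationResult:
    """The full outer protocol: repeated stratified half-splits, both ways.

    Each repeat draws one half-split, evaluates with part A as training and
    part B as test, then swaps the halves — giving ``2 * n_repeats`` runs.
    """
    labels = _check_features(features)
    counts = [int(np.sum(labels == c)) for c in np.unique(labels)]
    if len(counts) < 2 or min(counts) < 4:
        raise ValueError("cohort too small for stratified half-splits (need >= 4 per class)")

    ss = np.random.SeedSequence(config.seed)
    per_run: list[RunMetrics] = []
    selected: list[tuple] = []
    for r in range(n_repeats):
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        inner_seeds = child.generate_state(2) % (2**31)
        a, b = _half_split(labels, rng, flip=bool(r % 2))
        for (tr, te), iseed in zip(((a, b), (b, a)), inner_seeds):
            m, sel = evaluate_split(features, tr, te, config, inner_seed=int(iseed))
            per_run.append(m)
            selected.append(sel)
    return EvaluationResult(
        per_run=tuple(per_run),
        selected_per_run=tuple(selected),
        config=config,
        n_repeats=n_repeats,
    )


def paired_accuracy_test(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-run accuracies (same splits).

    Degenerate cases: all differences zero -> ``(nan, 1.0)``; nonzero
    constant differences -> ``(+/-inf, 0.0)``.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired accuracies")
    d = a - b
    if np.all(d == 0):
        return float("nan"), 1.0
    scale = np.max(np.abs(d))
    if np.std(d, ddof=1) <= 1e-12 * scale:  # constant nonzero differences
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)
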