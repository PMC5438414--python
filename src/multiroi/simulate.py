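"""Synthetic two-group cohorts with plantable ROI-level and connection-level
group differences.

The generator emulates the statistical structure the downstream analysis
assumes, not real anatomy: each ROI measure is drawn around a fixed
plausible baseline (log-normal for volumes and areas, normal for thickness),
and two kinds of group effects can be planted:

* **ROI effects** — the high-esteem group's mean for one (ROI, measure) pair
  is shifted by ``cohen_d`` baseline standard deviations.
* **Connection effects** — the high group's mean thickness at ROIs *i* and
  *j* is shifted by ``coupling_shift/2`` in opposite directions.  The
  thickness-similarity feature s(i,j) depends only on ``|t(i) - t(j)|`` and
  the within-ROI spreads, so widening that gap in one group moves s(i,j)
  differentially by group while each single-ROI shift stays comparatively
  small.

All randomness flows from one seed; identical specs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import N_CORTICAL_ROIS, builtin_atlas
from .cohort import Cohort, SubjectRecord

__all__ = ["EffectSpec", "GroundTruth", "generate_cohort", "null_permuted", "BASELINES"]

# measures an ROI effect may target (within-ROI thickness SD is never shifted)
EFFECT_MEASURES = ("gmv", "wmv", "csfv", "thk", "area")

# Fixed baseline scales (module constants, not fitted to anything).
# Volumes/areas: log-normal around a per-ROI median with log-scale sigma.
# Thickness: normal.  Units mm^3 / mm / mm^2.
BASELINES = {
    "gmv": {"median": 8000.0, "log_sigma": 0.25},
    "wmv": {"median": 6000.0, "log_sigma": 0.25},
    "csfv": {"median": 2000.0, "log_sigma": 0.30},
    "area": {"median": 2500.0, "log_sigma": 0.25},
    "thk": {"mean": 2.5, "sd": 0.25},
    "thksd": {"mean": 0.5, "sd": 0.10},
    "tiv": {"mean": 1.5e6, "sd": 1.0e5},
    "tsa": {"mean": 2.0e5, "sd": 1.5e4},
}

# Per-ROI baseline medians vary around the scale above by a fixed profile so
# ROIs are not interchangeable; the profile is a module constant drawn once
# from a hard-coded stream, independent of any user seed.
_PROFILE_RNG = np.random.default_rng(20170522)
_ROI_PROFILE = {
    m: np.exp(_PROFILE_RNG.normal(0.0, 0.3, N_CORTICAL_ROIS))
    for m in ("gmv", "wmv", "csfv", "area")
}
_THK_PROFILE = _PROFILE_RNG.normal(0.0, 0.15, N_CORTICAL_ROIS)  # additive, mm


def _lognormal_sd(median: float, log_sigma: float) -> float:
    """Standard deviation of a log-normal given its median and log-scale sd."""
    s2 = log_sigma**2
    return median * np.exp(s2 / 2.0) * np.sqrt(np.exp(s2) - 1.0)


@dataclass(frozen=True)
class EffectSpec:
    """Planted group differences and cohort shape for one simulation."""

    roi_effects: tuple[tuple[int, str, float], ...] = ()
    connection_effects: tuple[tuple[int, int, float], ...] = ()
    n_high: int = 34
    n_low: int = 34
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "roi_effects", tuple(tuple(e) for e in self.roi_effects))
        object.__setattr__(
            self, "connection_effects", tuple(tuple(e) for e in self.connection_effects)
        )
        if self.n_high < 2 or self.n_low < 2:
            raise ValueError("group sizes must be >= 2")
        for roi, measure, d in self.roi_effects:
            if not 1 <= roi <= N_CORTICAL_ROIS:
                raise ValueError(f"roi_effect index {roi} outside 1..{N_CORTICAL_ROIS}")
            if measure not in EFFECT_MEASURES:
                raise ValueError(f"roi_effect measure {measure!r} not in {EFFECT_MEASURES}")
        for i, j, shift in self.connection_effects:
            if not (1 <= i < j <= N_CORTICAL_ROIS):
                raise ValueError(f"connection_effect ({i},{j}) must satisfy 1 <= i < j <= 78")


@dataclass(frozen=True)
class GroundTruth:
    """The planted features, for recovery scoring."""

    true_roi_features: frozenset = field(default_factory=frozenset)
    true_similarity_features: frozenset = field(default_factory=frozenset)


def generate_cohort(spec: EffectSpec) -> tuple[Cohort, GroundTruth]:
    """Draw a two-group cohort realizing *spec*; also return its ground truth.

    Subjects are ordered high group first (ids ``high_001``...), then low.
    """
    atlas = builtin_atlas()
    n_rois = len(atlas)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_high + spec.n_low
    is_high = np.zeros(n, dtype=bool)
    is_high[: spec.n_high] = True

    draws: dict[str, np.ndarray] = {}
    for m in ("gmv", "wmv", "csfv", "area"):
        b = BASELINES[m]
        medians = b["median"] * _ROI_PROFILE[m]
        z = rng.normal(0.0, b["log_sigma"], (n, n_rois))
        draws[m] = medians[None, :] * np.exp(z)
    thk_mu = BASELINES["thk"]["mean"] + _THK_PROFILE
    draws["thk"] = thk_mu[None, :] + rng.normal(0.0, BASELINES["thk"]["sd"], (n, n_rois))
    draws["thksd"] = np.abs(
        rng.normal(BASELINES["thksd"]["mean"], BASELINES["thksd"]["sd"], (n, n_rois))
    )
    tiv = np.abs(rng.normal(BASELINES["tiv"]["mean"], BASELINES["tiv"]["sd"], n))
    tsa = np.abs(rng.normal(BASELINES["tsa"]["mean"], BASELINES["tsa"]["sd"], n))

    # ROI effects: additive shift of cohen_d baseline SDs in the high group.
    for roi, m, d in spec.roi_effects:
        b = BASELINES[m]
        if m == "thk":
            sd = b["sd"]
        else:
            sd = _lognormal_sd(b["median"] * _ROI_PROFILE[m][roi - 1], b["log_sigma"])
        draws[m][is_high, roi - 1] += d * sd

    # Connection effects: anti-correlated thickness shifts at i and j in the
    # high group only, each subject's pair pushed apart along that subject's
    # own gap so |t(i) - t(j)| widens by the full shift for every subject.
    # Group means move only through the slight asymmetry of the gap signs,
    # so single-ROI t-tests stay near the null while s(i,j) shifts strongly.
    for i, j, shift in spec.connection_effects:
        gap = draws["thk"][is_high, i - 1] - draws["thk"][is_high, j - 1]
        sign = np.where(gap >= 0, 1.0, -1.0)
        draws["thk"][is_high, i - 1] += sign * shift / 2.0
        draws["thk"][is_high, j - 1] -= sign * shift / 2.0

    np.clip(draws["thk"], 1e-3, None, out=draws["thk"])
    np.clip(draws["thksd"], 1e-3, None, out=draws["thksd"])

    subjects = []
    for s in range(n):
        group = "high" if is_high[s] else "low"
        k = s + 1 if is_high[s] else s - spec.n_high + 1
        subjects.append(
            SubjectRecord(
                subject_id=f"{group}_{k:03d}",
                group=group,
                roi_gm_volume=draws["gmv"][s],
                roi_wm_volume=draws["wmv"][s],
                roi_csf_volume=draws["csfv"][s],
                roi_thickness_mean=draws["thk"][s],
                roi_thickness_sd=draws["thksd"][s],
                roi_surface_area=draws["area"][s],
                total_intracranial_volume=float(tiv[s]),
                total_surface_area=float(tsa[s]),
            )
        )
    truth = GroundTruth(
        true_roi_features=frozenset((roi, m) for roi, m, _ in spec.roi_effects),
        true_similarity_features=frozenset((i, j) for i, j, _ in spec.connection_effects),
    )
    return Cohort(subjects=tuple(subjects), atlas=atlas), truth


def null_permuted(cohort: Cohort, seed: int) -> Cohort:
    """Return the cohort with group labels randomly permuted (data untouched)."""
    cohort.require_both_groups()
    rng = np.random.default_rng(seed)
    labels = list(cohort.groups)
    perm = rng.permutation(len(labels))
    shuffled = [labels[k] for k in perm]
    from dataclasses import replace

    subjects = tuple(
        replace(s, group=g) for s, g in zip(cohort.subjects, shuffled)
    )
    return Cohort(subjects=subjects, atlas=cohort.atlas)
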