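"""Feature engineering: measure normalization, the thickness-similarity map,
and subjects-by-features matrices.

Two families of features are built from ROI morphometry:

* **ROI features** — per-region gray/white/CSF volume, mean cortical
  thickness and surface area, normalized within subject (volumes by total
  intracranial volume, area by total surface area, thickness means by the
  standard deviation of the subject's 78 ROI thickness means).
* **Similarity features** — the Gaussian similarity of mean cortical
  thickness between every ROI pair,

  ``s(i,j) = exp(-(t(i) - t(j))^2 / (2 * (sd_i^2 + sd_j^2)))``

  a within-subject proxy for structural connectivity.  With 78 regions the
  78x78 symmetric map has 3003 strict-upper-triangle entries, vectorized
  row-major as (1,2), (1,3), ..., (77,78).

Similarity is computed from the raw (un-normalized) thickness means, since
its length scale is the within-ROI thickness spread, which rescaling the
means would no longer match; a switch allows using normalized means instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .atlas import AtlasTable, builtin_atlas
from .cohort import Cohort, SubjectRecord

__all__ = [
    "SimilarityMap",
    "FeatureMatrix",
    "FEATURE_TYPES",
    "ROI_FEATURE_TYPES",
    "normalize_subject",
    "normalize_cohort",
    "similarity",
    "similarity_map",
    "vectorize_upper_triangle",
    "devectorize_upper_triangle",
    "build_feature_matrix",
    "extract_features",
    "feature_label",
]

ROI_FEATURE_TYPES = ("gmv", "wmv", "csfv", "thickness", "area")
FEATURE_TYPES = ROI_FEATURE_TYPES + ("vol_union", "similarity")

# feature_type -> per-ROI measure code(s)
_TYPE_MEASURES = {
    "gmv": ("gmv",),
    "wmv": ("wmv",),
    "csfv": ("csfv",),
    "thickness": ("thk",),
    "area": ("area",),
    "vol_union": ("gmv", "wmv", "csfv"),
}

# Table-3-style single-letter measure suffixes
MEASURE_SUFFIX = {"gmv": "G", "wmv": "W", "csfv": "C", "thk": "T", "area": "A"}


def normalize_subject(record: SubjectRecord) -> SubjectRecord:
    """Within-subject normalization of the five ROI measures.

    Tissue volumes are divided by total intracranial volume, surface area by
    total surface area, and each ROI's mean thickness by the standard
    deviation (ddof=1) of the subject's ROI thickness means.  The within-ROI
    thickness SD and the subject totals are left unchanged.
    """
    thk_sd = float(np.std(record.roi_thickness_mean, ddof=1))
    if thk_sd <= 0:
        raise ValueError(
            f"subject {record.subject_id!r}: SD of ROI thickness means is zero; "
            "cannot normalize thickness"
        )
    return record.with_measures(
        gmv=record.roi_gm_volume / record.total_intracranial_volume,
        wmv=record.roi_wm_volume / record.total_intracranial_volume,
        csfv=record.roi_csf_volume / record.total_intracranial_volume,
        thk=record.roi_thickness_mean / thk_sd,
        area=record.roi_surface_area / record.total_surface_area,
    )


def normalize_cohort(cohort: Cohort) -> Cohort:
    return replace(cohort, subjects=tuple(normalize_subject(s) for s in cohort))


def similarity(t_i: float, t_j: float, sd_i: float, sd_j: float) -> float:
    """Gaussian thickness similarity of two ROIs.

    ``exp(-(t_i - t_j)^2 / (2 sigma^2))`` with ``sigma^2 = sd_i^2 + sd_j^2``.
    Symmetric in (i, j); equals 1 when the thicknesses agree; invariant
    under a common rescaling of all four arguments.
    """
    s2 = sd_i**2 + sd_j**2
    if s2 <= 0:
        raise ValueError("sd_i and sd_j are both zero: similarity scale undefined")
    return math.exp(-((t_i - t_j) ** 2) / (2.0 * s2))


@dataclass(frozen=True)
class SimilarityMap:
    """One subject's symmetric ROI-by-ROI thickness-similarity matrix."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = v.shape[0]
        if v.shape != (n, n):
            raise ValueError("similarity map must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity map must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity map diagonal must be 1")
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise ValueError("similarity values must lie in (0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path, atlas: AtlasTable | None = None) -> None:
        labels = (atlas or builtin_atlas()).labels[: self.n_rois]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path, sep="\t")


def similarity_map(record: SubjectRecord, use_normalized_thickness: bool = False) -> SimilarityMap:
    """The full pairwise similarity map for one subject.

    By default raw thickness means are used; set ``use_normalized_thickness``
    to compute the map from a normalized record's thickness means instead
    (the within-ROI SDs are used as-is either way).
    """
    t = record.roi_thickness_mean
    if use_normalized_thickness:
        t = normalize_subject(record).roi_thickness_mean
    sd2 = record.roi_thickness_sd**2
    s2 = sd2[:, None] + sd2[None, :]
    off = ~np.eye(len(t), dtype=bool)
    if np.any(s2[off] <= 0):
        raise ValueError(
            f"subject {record.subject_id!r}: an ROI pair has zero combined thickness SD"
        )
    diff = t[:, None] - t[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.exp(-(diff**2) / (2.0 * s2))
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry against fp noise
    return SimilarityMap(values=vals, subject_id=record.subject_id)


def vectorize_upper_triangle(smap: SimilarityMap) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-major strict upper triangle of the map, with (i, j) feature ids.

    For 78 ROIs this yields 78*77/2 = 3003 values ordered
    (1,2), (1,3), ..., (1,78), (2,3), ..., (77,78) (1-based ROI indices).
    """
    n = smap.n_rois
    iu, ju = np.triu_indices(n, k=1)
    vec = smap.values[iu, ju]
    ids = [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]
    return vec, ids


def devectorize_upper_triangle(vec: np.ndarray, subject_id: str = "") -> SimilarityMap:
    """Inverse of :func:`vectorize_upper_triangle` (diagonal restored to 1)."""
    vec = np.asarray(vec, dtype=float)
    m = len(vec)
    n = int(round((1 + math.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a strict upper-triangle size")
    vals = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    vals[iu, ju] = vec
    vals[ju, iu] = vec
    return SimilarityMap(values=vals, subject_id=subject_id)


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects-by-features matrix for one feature type.

    ``feature_ids`` are ``(roi_index, measure)`` tuples for ROI features and
    ``(i, j)`` ROI-index pairs (i < j) for similarity features; ``labels``
    are +1 for the high group and -1 for the low group.
    """

    values: np.ndarray
    feature_ids: tuple
    feature_type: str
    subject_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        n, p = self.values.shape
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length must equal the number of columns")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature_ids")
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels length must equal the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            subject_ids=tuple(self.subject_ids[k] for k in idx),
            labels=self.labels[idx],
        )

    def subset_features(self, ids) -> "FeatureMatrix":
        pos = {f: k for k, f in enumerate(self.feature_ids)}
        cols = [pos[f] for f in ids]
        return replace(self, values=self.values[:, cols], feature_ids=tuple(ids))

    def column_labels(self, atlas: AtlasTable | None = None) -> list[str]:
        atlas = atlas or builtin_atlas()
        return [feature_label(f, atlas, style="short") for f in self.feature_ids]

    def to_tsv(self, path, atlas: AtlasTable | None = None) -> None:
        df = pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=self.column_labels(atlas)
        )
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index_label="subject_id")


def feature_label(feature_id, atlas: AtlasTable | None = None, style: str = "short") -> str:
    """Render a feature id as text.

    ROI features: ``MFG_R_W`` (short) or ``Middle frontal gyrus_R_W`` (long).
    Similarity features: ``ACG_L|MOG_L`` (short) or
    ``Anterior cingulate gyrus_L-Middle occipital gyrus_L`` (long).
    """
    atlas = atlas or builtin_atlas()
    a, b = feature_id
    if isinstance(b, str):  # (roi_index, measure)
        e = atlas[a]
        region = e.abbreviation if style == "short" else e.name
        return f"{region}_{e.hemi_code}_{MEASURE_SUFFIX[b]}"
    ei, ej = atlas[a], atlas[b]
    if style == "short":
        return f"{ei.label}|{ej.label}"
    return f"{ei.name}_{ei.hemi_code}-{ej.name}_{ej.hemi_code}"


def build_feature_matrix(
    cohort: Cohort,
    feature_type: str,
    *,
    normalize: bool = True,
    similarity_from_normalized: bool = False,
) -> FeatureMatrix:
    """Assemble the subjects-by-features matrix for one feature type.

    Single-measure types give 78 columns; ``vol_union`` concatenates the
    three normalized tissue-volume blocks (234 columns); ``similarity``
    vectorizes each subject's map (3003 columns).  Labels are +1 for the
    high group, -1 for the low group.
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"unknown feature_type {feature_type!r}; one of {FEATURE_TYPES}")
    labels = np.array([1 if s.group == "high" else -1 for s in cohort])
    subject_ids = tuple(cohort.subject_ids)

    if feature_type == "similarity":
        rows, ids = [], None
        for s in cohort:
            vec, ids = vectorize_upper_triangle(
                similarity_map(s, use_normalized_thickness=similarity_from_normalized)
            )
            rows.append(vec)
        n_pairs = len(cohort.atlas) * (len(cohort.atlas) - 1) // 2
        values = np.vstack(rows) if rows else np.empty((0, n_pairs))
        if ids is None:
            iu, ju = np.triu_indices(len(cohort.atlas), k=1)
            ids = [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]
        return FeatureMatrix(values, tuple(ids), "similarity", subject_ids, labels)

    source = normalize_cohort(cohort) if normalize else cohort
    blocks, ids = [], []
    for m in _TYPE_MEASURES[feature_type]:
        block = (
            np.vstack([s.measure(m) for s in source])
            if len(source)
            else np.empty((0, len(cohort.atlas)))
        )
        blocks.append(block)
        ids.extend((e.index, m) for e in cohort.atlas)
    return FeatureMatrix(np.hstack(blocks), tuple(ids), feature_type, subject_ids, labels)


def extract_features(
    cohort: Cohort,
    feature_types=ROI_FEATURE_TYPES + ("similarity",),
    **kwargs,
) -> dict[str, FeatureMatrix]:
    """Build the per-type feature matrices the classifier consumes."""
    cohort.require_both_groups()
    return {ft: build_feature_matrix(cohort, ft, **kwargs) for ft in feature_types}
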