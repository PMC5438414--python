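"""Subject-level data model and flat-file cohort I/O.

A subject is a row of ROI-level morphometry: six per-ROI measures over the
78 cortical AAL regions plus two whole-head totals and a binary group
label.  Cohorts are exchanged as CSV/TSV with one row per subject and
columns named ``<ABBREV>_<L|R>_<measure>`` (measures ``gmv``, ``wmv``,
``csfv``, ``thk``, ``thksd``, ``area``) plus ``subject_id``, ``group``,
``tiv`` and ``tsa``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasTable, builtin_atlas

__all__ = [
    "MEASURES",
    "GROUPS",
    "SubjectRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

#: per-ROI measure codes, in canonical column order
MEASURES = ("gmv", "wmv", "csfv", "thk", "thksd", "area")
GROUPS = ("high", "low")

_MEASURE_ATTR = {
    "gmv": "roi_gm_volume",
    "wmv": "roi_wm_volume",
    "csfv": "roi_csf_volume",
    "thk": "roi_thickness_mean",
    "thksd": "roi_thickness_sd",
    "area": "roi_surface_area",
}
# measures that must be strictly positive (vs merely non-negative)
_STRICT_POSITIVE = {"thk", "area"}


class CohortValidationError(ValueError):
    """A cohort table or record violates the data model."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's ROI morphometry, whole-head totals and group label.

    All six ROI vectors follow the atlas index order (AAL 1..78).  Volumes
    are mm^3, thickness mm, areas mm^2 — until normalized, after which the
    volume and area measures are unitless fractions of the subject totals.
    """

    subject_id: str
    group: str
    roi_gm_volume: np.ndarray
    roi_wm_volume: np.ndarray
    roi_csf_volume: np.ndarray
    roi_thickness_mean: np.ndarray
    roi_thickness_sd: np.ndarray
    roi_surface_area: np.ndarray
    total_intracranial_volume: float
    total_surface_area: float

    def __post_init__(self):
        for m, attr in _MEASURE_ATTR.items():
            v = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, v)
        self.validate(n_rois=len(self.roi_gm_volume))

    def validate(self, n_rois: int) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        for m, attr in _MEASURE_ATTR.items():
            v = getattr(self, attr)
            if v.shape != (n_rois,):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: {attr} has shape {v.shape}, "
                    f"expected ({n_rois},)"
                )
            if not np.all(np.isfinite(v)):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: non-finite value in {attr}"
                )
            if m in _STRICT_POSITIVE:
                if np.any(v <= 0):
                    raise CohortValidationError(
                        f"subject {self.subject_id!r}: {attr} must be > 0"
                    )
            elif np.any(v < 0):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: {attr} must be >= 0"
                )
        if not self.total_intracranial_volume > 0:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: total_intracranial_volume must be > 0"
            )
        if not self.total_surface_area > 0:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: total_surface_area must be > 0"
            )

    def measure(self, measure: str) -> np.ndarray:
        """The per-ROI vector for a measure code (``gmv`` ... ``area``)."""
        return getattr(self, _MEASURE_ATTR[measure])

    def with_measures(self, **updates: np.ndarray) -> "SubjectRecord":
        """Copy with some per-ROI measure vectors replaced (by measure code)."""
        return replace(self, **{_MEASURE_ATTR[m]: v for m, v in updates.items()})


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of subjects over a shared atlas."""

    subjects: tuple[SubjectRecord, ...]
    atlas: AtlasTable = field(default_factory=builtin_atlas)

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise CohortValidationError(f"duplicate subject_id(s): {sorted(dup)}")
        n = len(self.atlas)
        for s in self.subjects:
            s.validate(n_rois=n)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def group_counts(self) -> dict[str, int]:
        g = self.groups
        return {k: g.count(k) for k in GROUPS}

    def require_both_groups(self) -> None:
        counts = self.group_counts()
        if min(counts.values()) == 0:
            raise CohortValidationError(
                f"both group labels required for classification; counts {counts}"
            )


def _roi_columns(atlas: AtlasTable) -> dict[str, list[str]]:
    return {m: [f"{lab}_{m}" for lab in atlas.labels] for m in MEASURES}


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    cols = _roi_columns(cohort.atlas)
    data: dict[str, list] = {
        "subject_id": cohort.subject_ids,
        "group": cohort.groups,
        "tiv": [s.total_intracranial_volume for s in cohort],
        "tsa": [s.total_surface_area for s in cohort],
    }
    for m in MEASURES:
        block = (
            np.vstack([s.measure(m) for s in cohort])
            if len(cohort)
            else np.empty((0, len(cohort.atlas)))
        )
        for j, c in enumerate(cols[m]):
            data[c] = block[:, j]
    return pd.DataFrame(data)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (or TSV if the path ends in ``.tsv``)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)


def read_cohort(path, atlas: AtlasTable | None = None) -> Cohort:
    """Read and validate a cohort table written by :func:`write_cohort`.

    Raises :class:`CohortValidationError` naming the offending column or row
    on any schema violation (missing column, non-numeric cell, bad group
    label, negative measure, duplicate subject id).
    """
    if atlas is None:
        atlas = builtin_atlas()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(
        path, sep=sep, dtype={"subject_id": str, "group": str},
        float_precision="round_trip",
    )

    required = ["subject_id", "group", "tiv", "tsa"]
    roi_cols = _roi_columns(atlas)
    for m in MEASURES:
        required.extend(roi_cols[m])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"missing column(s): {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )

    numeric_cols = [c for c in required if c not in ("subject_id", "group")]
    for c in numeric_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad) or coerced.isna().any():
            row = int((bad if len(bad) else df.index[coerced.isna()])[0])
            raise CohortValidationError(f"non-numeric or missing value in column {c!r}, row {row}")
        df[c] = coerced

    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                total_intracranial_volume=float(row["tiv"]),
                total_surface_area=float(row["tsa"]),
                **{
                    _MEASURE_ATTR[m]: row[roi_cols[m]].to_numpy(dtype=float)
                    for m in MEASURES
                },
            )
        )
    return Cohort(subjects=tuple(subjects), atlas=atlas)
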