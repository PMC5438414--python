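"""Built-in cortical atlas: the 78 cortical AAL regions.

The Automated Anatomical Labeling (AAL) template defines 45 labeled regions
per hemisphere (90 in total).  Subcortical structures are not part of the
cortical-morphometry analysis, so the 12 subcortical labels are dropped and
the remaining 78 cortical regions — 39 paired region names — form the atlas
used throughout this package.  By AAL convention odd indices are left
hemisphere and even indices are right, and every vector or matrix axis in
the package follows this index order (1..78).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import pandas as pd

__all__ = [
    "AtlasEntry",
    "AtlasTable",
    "builtin_atlas",
    "N_CORTICAL_ROIS",
    "N_SUBCORTICAL_EXCLUDED",
    "aal_labels_per_hemisphere",
]

#: number of cortical regions retained in the built-in atlas
N_CORTICAL_ROIS = 78
#: subcortical AAL labels excluded from the cortical analysis
N_SUBCORTICAL_EXCLUDED = 12

HEMISPHERES = ("left", "right")
LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic", "central", "insula")


@dataclass(frozen=True)
class AtlasEntry:
    """One cortical region: AAL index, full name, short code, hemisphere, lobe."""

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    lobe: str

    @property
    def hemi_code(self) -> str:
        return "L" if self.hemisphere == "left" else "R"

    @property
    def label(self) -> str:
        """Short label like ``MFG_R``."""
        return f"{self.abbreviation}_{self.hemi_code}"


# (name, abbreviation, lobe) for each bilateral pair, in AAL index order:
# pair k occupies indices (2k+1, 2k+2) = (left, right).
_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("Precentral gyrus", "PreCG", "central"),
    ("Superior frontal gyrus (dorsal)", "SFGdor", "frontal"),
    ("Orbitofrontal cortex (superior)", "ORBsup", "frontal"),
    ("Middle frontal gyrus", "MFG", "frontal"),
    ("Orbitofrontal cortex (middle)", "ORBmid", "frontal"),
    ("Inferior frontal gyrus (opercular)", "IFGoperc", "frontal"),
    ("Inferior frontal gyrus (triangular)", "IFGtriang", "frontal"),
    ("Orbitofrontal cortex (inferior)", "ORBinf", "frontal"),
    ("Rolandic operculum", "ROL", "central"),
    ("Supplementary motor area", "SMA", "frontal"),
    ("Olfactory", "OLF", "frontal"),
    ("Superior frontal gyrus (medial)", "SFGmed", "frontal"),
    ("Orbitofrontal cortex (medial)", "ORBmed", "frontal"),
    ("Rectus gyrus", "REC", "frontal"),
    ("Insula", "INS", "insula"),
    ("Anterior cingulate gyrus", "ACG", "limbic"),
    ("Middle cingulate gyrus", "MCG", "limbic"),
    ("Posterior cingulate gyrus", "PCG", "limbic"),
    ("ParaHippocampal gyrus", "PHG", "limbic"),
    ("Calcarine cortex", "CAL", "occipital"),
    ("Cuneus", "CUN", "occipital"),
    ("Lingual gyrus", "LING", "occipital"),
    ("Superior occipital gyrus", "SOG", "occipital"),
    ("Middle occipital gyrus", "MOG", "occipital"),
    ("Inferior occipital gyrus", "IOG", "occipital"),
    ("Fusiform gyrus", "FFG", "occipital"),
    ("Postcentral gyrus", "PoCG", "central"),
    ("Superior parietal gyrus", "SPG", "parietal"),
    ("Inferior parietal lobule", "IPL", "parietal"),
    ("Supramarginal gyrus", "SMG", "parietal"),
    ("Angular gyrus", "ANG", "parietal"),
    ("Precuneus", "PCUN", "parietal"),
    ("Paracentral lobule", "PCL", "frontal"),
    ("Heschl gyrus", "HES", "temporal"),
    ("Superior temporal gyrus", "STG", "temporal"),
    ("Temporal pole (superior)", "TPOsup", "limbic"),
    ("Middle temporal gyrus", "MTG", "temporal"),
    ("Temporal pole (middle)", "TPOmid", "limbic"),
    ("Inferior temporal gyrus", "ITG", "temporal"),
)

assert len(_PAIRS) * 2 == N_CORTICAL_ROIS


class AtlasTable:
    """Immutable, index-ordered collection of :class:`AtlasEntry`.

    Supports iteration, ``len``, lookup by 1-based AAL index
    (``atlas[7]``), and lookup by short label (``atlas.by_label("MFG_L")``).
    """

    def __init__(self, entries: tuple[AtlasEntry, ...]):
        self._entries = tuple(entries)
        self._by_index = {e.index: e for e in self._entries}
        self._by_label = {e.label: e for e in self._entries}
        if len(self._by_label) != len(self._entries):
            raise ValueError("duplicate (abbreviation, hemisphere) labels in atlas")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[AtlasEntry]:
        return iter(self._entries)

    def __getitem__(self, index: int) -> AtlasEntry:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no ROI with AAL index {index}") from None

    def by_label(self, label: str) -> AtlasEntry:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no ROI with label {label!r}") from None

    @property
    def entries(self) -> tuple[AtlasEntry, ...]:
        return self._entries

    @property
    def labels(self) -> tuple[str, ...]:
        """Short labels (``PreCG_L``, ``PreCG_R``, ...) in index order."""
        return tuple(e.label for e in self._entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self._entries],
                "name": [e.name for e in self._entries],
                "abbreviation": [e.abbreviation for e in self._entries],
                "hemisphere": [e.hemisphere for e in self._entries],
                "lobe": [e.lobe for e in self._entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, AtlasTable) and self._entries == other._entries

    def __hash__(self) -> int:
        return hash(self._entries)


def _build() -> AtlasTable:
    entries = []
    for k, (name, abbrev, lobe) in enumerate(_PAIRS):
        entries.append(AtlasEntry(2 * k + 1, name, abbrev, "left", lobe))
        entries.append(AtlasEntry(2 * k + 2, name, abbrev, "right", lobe))
    return AtlasTable(tuple(entries))


_BUILTIN = _build()


def builtin_atlas() -> AtlasTable:
    """The 78-region cortical AAL atlas (identical object on every call)."""
    return _BUILTIN


def aal_labels_per_hemisphere() -> int:
    """Labels per hemisphere in the source AAL template (cortical + subcortical)."""
    return (N_CORTICAL_ROIS + N_SUBCORTICAL_EXCLUDED) // 2
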