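"""Region sets: named, ordered lists of region labels used as network nodes.

Two configurable defaults ship with the package: an 82-node whole-brain set
(68 Desikan-Killiany cortical labels plus 14 subcortical structures) and a
50-node thalamic set (25 FreeSurfer-7 style nuclei per hemisphere). Both are
stand-ins: real analyses should pass the label list matching their own volume
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "RegionSet",
    "default_global_regions",
    "default_thalamic_regions",
]

_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_SUBCORTICAL = [
    "Thalamus", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens",
]

# FreeSurfer 7 thalamic-nuclei segmentation labels (one hemisphere).
_THALAMIC_NUCLEI = [
    "AV", "CeM", "CL", "CM", "LD", "LGN", "LP", "L-Sg",
    "MDl", "MDm", "MGN", "MV-Re", "Pc", "Pf", "Pt",
    "PuA", "PuI", "PuL", "PuM", "VA", "VAmc", "VLa", "VLp", "VM", "VPL",
]


@dataclass(frozen=True)
class RegionSet:
    """An ordered, duplicate-free collection of region labels.

    Parameters
    ----------
    name:
        Network identifier, e.g. ``"global"`` or ``"thalamic"``.
    regions:
        Ordered region labels; order is preserved through the whole pipeline.
    hemispheres:
        Optional per-region ``"L"``/``"R"`` tags, same length as ``regions``.
    """

    name: str
    regions: tuple[str, ...]
    hemispheres: Optional[tuple[str, ...]] = field(default=None)

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        object.__setattr__(self, "regions", regions)
        if len(regions) < 3:
            raise ValueError(
                f"RegionSet {self.name!r} needs at least 3 regions, got {len(regions)}"
            )
        if len(set(regions)) != len(regions):
            dupes = sorted({r for r in regions if regions.count(r) > 1})
            raise ValueError(f"duplicate region labels in {self.name!r}: {dupes}")
        if self.hemispheres is not None:
            hemis = tuple(self.hemispheres)
            object.__setattr__(self, "hemispheres", hemis)
            if len(hemis) != len(regions):
                raise ValueError("hemispheres length must match regions length")
            bad = sorted({h for h in hemis if h not in ("L", "R")})
            if bad:
                raise ValueError(f"hemisphere tags must be 'L' or 'R', got {bad}")

    def __len__(self) -> int:
        return len(self.regions)

    def index(self, label: str) -> int:
        return self.regions.index(label)

    def subset(self, labels: Sequence[str], name: Optional[str] = None) -> "RegionSet":
        """New RegionSet keeping only ``labels``, in the order given."""
        missing = [lab for lab in labels if lab not in self.regions]
        if missing:
            raise KeyError(f"regions not in {self.name!r}: {missing}")
        hemis = None
        if self.hemispheres is not None:
            lookup = dict(zip(self.regions, self.hemispheres))
            hemis = tuple(lookup[lab] for lab in labels)
        return RegionSet(name or self.name, tuple(labels), hemis)


def _bilateral(labels: Sequence[str]) -> tuple[list[str], list[str]]:
    names, hemis = [], []
    for side, tag in (("lh", "L"), ("rh", "R")):
        for lab in labels:
            names.append(f"{side}_{lab}")
            hemis.append(tag)
    return names, hemis


def default_global_regions() -> RegionSet:
    """82-node whole-brain set: 68 cortical + 14 subcortical labels."""
    cort, cort_h = _bilateral(_DK_CORTICAL)
    sub, sub_h = _bilateral(_SUBCORTICAL)
    return RegionSet("global", tuple(cort + sub), tuple(cort_h + sub_h))


def default_thalamic_regions() -> RegionSet:
    """50-node thalamic set: 25 nuclei per hemisphere."""
    names, hemis = _bilateral(_THALAMIC_NUCLEI)
    return RegionSet("thalamic", tuple(names), tuple(hemis))
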