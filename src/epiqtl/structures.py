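"""Core data containers: linkage maps, QTL positions, full-sib family datasets.

A full-sib family from an outbred cross segregates at fully informative
markers: parent P1 is heterozygous 1/2 and parent P2 is 3/4, so every
offspring carries one P1 allele in {1, 2} and one P2 allele in {3, 4}.
Genotypes are therefore stored as two integer matrices (one per parent),
which also encode the grandparental origin of each transmitted allele when
the parental linkage phases are known (the convention used throughout:
origin 0 corresponds to allele 1 resp. 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LinkageGroup",
    "LinkageMap",
    "QtlPosition",
    "FamilyDataset",
]


@dataclass(frozen=True)
class LinkageGroup:
    """One linkage group: ordered markers with map positions in cM."""

    name: str
    markers: tuple[str, ...]
    positions: np.ndarray  # cM, strictly increasing

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.markers) != pos.size:
            raise ValueError(
                f"group {self.name!r}: {len(self.markers)} marker names "
                f"but {pos.size} positions"
            )
        if pos.size < 2:
            raise ValueError(f"group {self.name!r}: needs at least 2 markers")
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"group {self.name!r}: positions must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def contains(self, position_cm: float) -> bool:
        lo, hi = self.span
        return lo <= position_cm <= hi


@dataclass(frozen=True)
class LinkageMap:
    """Ordered collection of linkage groups.

    Marker columns of a genotype matrix follow the group order given here,
    with markers within a group in map order.
    """

    groups: tuple[LinkageGroup, ...]

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in map")
        all_markers = [m for g in self.groups for m in g.markers]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("duplicate marker names in map")

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m for g in self.groups for m in g.markers)

    def group(self, name: str) -> LinkageGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown linkage group {name!r}")

    def marker_slice(self, name: str) -> slice:
        """Column slice of the concatenated marker matrix for one group."""
        start = 0
        for g in self.groups:
            if g.name == name:
                return slice(start, start + len(g.markers))
            start += len(g.markers)
        raise KeyError(f"unknown linkage group {name!r}")


@dataclass(frozen=True)
class QtlPosition:
    """A putative QTL location: linkage group plus position in cM."""

    group: str
    position_cm: float

    def __str__(self) -> str:  # used in result tables and logs
        return f"{self.group}:{self.position_cm:g}"


@dataclass
class FamilyDataset:
    """Linkage map, offspring marker genotypes and phenotypes of one family.

    ``p1_alleles``/``p2_alleles`` are (n, m) integer matrices holding, for
    each offspring and marker, the allele transmitted by parent P1 (1 or 2)
    and by parent P2 (3 or 4).  ``truth``, when present, records simulator
    ground truth (true QTL positions, per-offspring two-locus genotype
    indices, residual variance).
    """

    linkage_map: LinkageMap
    ids: np.ndarray
    p1_alleles: np.ndarray
    p2_alleles: np.ndarray
    phenotypes: np.ndarray
    truth: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.p1_alleles = np.asarray(self.p1_alleles, dtype=np.int8)
        self.p2_alleles = np.asarray(self.p2_alleles, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        n = self.phenotypes.size
        m = self.linkage_map.n_markers
        if self.ids.size != n:
            raise ValueError("ids and phenotypes disagree on family size")
        if self.p1_alleles.shape != (n, m) or self.p2_alleles.shape != (n, m):
            raise ValueError(
                f"genotype matrices must be ({n}, {m}); got "
                f"{self.p1_alleles.shape} and {self.p2_alleles.shape}"
            )
        if not np.isin(self.p1_alleles, (1, 2)).all():
            raise ValueError("P1 alleles must be 1 or 2")
        if not np.isin(self.p2_alleles, (3, 4)).all():
            raise ValueError("P2 alleles must be 3 or 4")
        if not np.isfinite(self.phenotypes).all():
            raise ValueError("phenotypes must be finite")

    @property
    def n(self) -> int:
        return int(self.phenotypes.size)

    def marker_origins(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Grandparental origins (0/1) of the transmitted alleles per parent."""
        cols = self.linkage_map.marker_slice(group)
        return (
            (self.p1_alleles[:, cols] - 1).astype(np.int64),
            (self.p2_alleles[:, cols] - 3).astype(np.int64),
        )
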