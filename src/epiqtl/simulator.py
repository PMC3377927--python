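"""Simulation of full-sib families segregating for two epistatic QTLs.

Meiosis in each parent is a Markov chain of grandparental origins along
every linkage group (Haldane map function, no interference).  Each
offspring receives one P1 gamete (alleles 1/2) and one P2 gamete (alleles
3/4); phenotypes are the true two-locus genotypic value plus a normal
residual whose variance is set from the requested heritability.

The :func:`benchmark_design` preset mirrors the reference simulation
study: a 100 cM group with six equidistant markers, QTLs at 30 and 70 cM,
and a fixed 16-effect vector spanning all additive, dominance and
epistatic components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_model import EFFECT_NAMES, effects_to_genotype_values, genetic_variance
from .qtl_probs import haldane_r
from .structures import FamilyDataset, LinkageGroup, LinkageMap, QtlPosition

__all__ = [
    "SimulationConfig",
    "BENCHMARK_EFFECTS",
    "benchmark_design",
    "residual_variance_for_h2",
    "simulate_gamete",
    "simulate_family",
]

#: True effect vector of the benchmark simulation design, in
#: :data:`~epiqtl.genetic_model.EFFECT_NAMES` order.
BENCHMARK_EFFECTS: np.ndarray = np.array(
    [50.0, 2.0, 3.0, 4.0, -3.0, 1.0, -2.5,
     -2.0, 2.5, -3.0, 3.5, -4.0, -4.5, -2.0, 2.5, -5.0]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated family."""

    linkage_map: LinkageMap
    qtl1: QtlPosition
    qtl2: QtlPosition
    effects: np.ndarray  # 16 effects in EFFECT_NAMES order
    heritability: float
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if self.effects.shape != (16,):
            raise ValueError(f"effects must have 16 entries ({EFFECT_NAMES})")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie strictly between 0 and 1")
        if self.n < 1:
            raise ValueError("family size must be at least 1")
        for q in (self.qtl1, self.qtl2):
            if not self.linkage_map.group(q.group).contains(q.position_cm):
                raise ValueError(f"QTL position {q} outside its group's marker span")


def benchmark_design(n: int, heritability: float, seed: int | None = None) -> SimulationConfig:
    """The standard benchmark design: 100 cM group, 6 equidistant markers
    (0, 20, ..., 100 cM), QTLs at 30 and 70 cM, :data:`BENCHMARK_EFFECTS`."""
    group = LinkageGroup(
        name="LG1",
        markers=tuple(f"M{i + 1}" for i in range(6)),
        positions=np.arange(0.0, 101.0, 20.0),
    )
    return SimulationConfig(
        linkage_map=LinkageMap(groups=(group,)),
        qtl1=QtlPosition("LG1", 30.0),
        qtl2=QtlPosition("LG1", 70.0),
        effects=BENCHMARK_EFFECTS.copy(),
        heritability=heritability,
        n=n,
        seed=seed,
    )


def residual_variance_for_h2(effects: np.ndarray, h2: float) -> float:
    """Residual variance giving heritability ``h2`` for the QTL effects.

    sigma^2 = V_g (1 - h2) / h2, with V_g the genetic variance of the 16
    genotypic values under equal genotype frequencies.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie strictly between 0 and 1")
    return genetic_variance(effects) * (1.0 - h2) / h2


def simulate_gamete(
    positions: np.ndarray, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Grandparental origins of ``size`` gametes at ordered loci positions.

    The first locus is a fair coin; each successive origin flips with
    probability given by Haldane's function of the inter-locus distance.
    Returns a (size, n_loci) 0/1 matrix.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("at least one locus required")
    if np.any(np.diff(positions) < 0):
        raise ValueError("locus positions must be ordered")
    r = haldane_r(np.diff(positions))
    origins = np.empty((size, positions.size), dtype=np.int64)
    origins[:, 0] = rng.integers(0, 2, size=size)
    flips = rng.random((size, positions.size - 1)) < r[None, :]
    if positions.size > 1:
        origins[:, 1:] = flips
        np.cumsum(origins, axis=1, out=origins)
        origins &= 1
    return origins


def simulate_family(config: SimulationConfig) -> FamilyDataset:
    """Simulate one full-sib family under ``config``.

    The returned dataset records, under ``truth``, the true QTL positions,
    the per-offspring two-locus genotype index (canonical order), the
    genotypic values, the realised residual variance and the seed.
    """
    rng = np.random.default_rng(config.seed)
    lm = config.linkage_map
    n = config.n

    qtls_by_group: dict[str, list[tuple[int, float]]] = {}
    for k, q in enumerate((config.qtl1, config.qtl2)):
        qtls_by_group.setdefault(q.group, []).append((k, q.position_cm))

    m = lm.n_markers
    p1 = np.empty((n, m), dtype=np.int8)
    p2 = np.empty((n, m), dtype=np.int8)
    qtl_origin_p1 = np.empty((n, 2), dtype=np.int64)
    qtl_origin_p2 = np.empty((n, 2), dtype=np.int64)

    for group in lm.groups:
        cols = lm.marker_slice(group.name)
        qtls = sorted(qtls_by_group.get(group.name, []), key=lambda t: t[1])
        all_pos = np.sort(np.concatenate([group.positions, [p for _, p in qtls]]))
        # indices of the QTL loci within the merged, sorted locus list; a QTL
        # coinciding with a marker sits immediately after it (stable sort)
        qtl_loc = np.searchsorted(group.positions, [p for _, p in qtls], side="right")
        qtl_loc = qtl_loc + np.arange(len(qtls))
        marker_loc = np.setdiff1d(np.arange(all_pos.size), qtl_loc)

        for parent, (markers, qtl_origins) in enumerate(
            ((p1, qtl_origin_p1), (p2, qtl_origin_p2))
        ):
            origins = simulate_gamete(all_pos, rng, size=n)
            base = 1 if parent == 0 else 3
            markers[:, cols] = (origins[:, marker_loc] + base).astype(np.int8)
            for (k, _), loc in zip(qtls, qtl_loc):
                qtl_origins[:, k] = origins[:, loc]

    # two-locus genotype index: locus index = 2*p1_origin + p2_origin
    iq1 = 2 * qtl_origin_p1[:, 0] + qtl_origin_p2[:, 0]
    iq2 = 2 * qtl_origin_p1[:, 1] + qtl_origin_p2[:, 1]
    genotype_index = 4 * iq1 + iq2

    u = effects_to_genotype_values(config.effects)
    sigma2 = residual_variance_for_h2(config.effects, config.heritability)
    phenotypes = u[genotype_index] + rng.normal(0.0, np.sqrt(sigma2), size=n)

    return FamilyDataset(
        linkage_map=lm,
        ids=np.array([f"ind{i + 1}" for i in range(n)]),
        p1_alleles=p1,
        p2_alleles=p2,
        phenotypes=phenotypes,
        truth={
            "qtl1": config.qtl1,
            "qtl2": config.qtl2,
            "effects": np.asarray(config.effects).copy(),
            "genotype_index": genotype_index,
            "genotype_values": u,
            "sigma2": sigma2,
            "heritability": config.heritability,
            "seed": config.seed,
        },
    )
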