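"""Orthogonal genetic-effect decomposition for one and two multiallelic QTLs.

In a full-sib family from two outbred parents, a QTL with parental
genotypes 1/2 x 3/4 segregates into four offspring genotypes 13, 14, 23,
24.  The genotypic value decomposes into an overall mean, two additive
effects (alpha for the P1 allele substitution 1 -> 2, beta for the P2
substitution 3 -> 4) and one dominance effect gamma (interaction of the two
parental alleles).  For two QTLs the 16 two-locus genotypic values
decompose into 16 orthogonal effects: the mean, six main effects, and nine
epistatic effects split by parental origin — additive x additive (I),
additive x dominance (J), dominance x additive (K) and dominance x
dominance (L).

Effects and genotypic values are connected by an orthogonal +/-1 design
matrix ``D`` with ``u = D a`` and ``a = D^T u / 16``; each non-intercept
column of ``D`` is simultaneously the contrast vector of the null
hypothesis "this effect is zero", expressed on the genotypic values as
``c^T u = 0``.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "LOCUS_GENOTYPES",
    "TWO_LOCUS_GENOTYPES",
    "EFFECT_NAMES",
    "EffectContrast",
    "single_locus_design_matrix",
    "two_locus_design_matrix",
    "effects_to_genotype_values",
    "genotype_values_to_effects",
    "effect_contrast",
    "genetic_variance",
]

#: Canonical order of the four genotypes at one locus (P1 allele, P2 allele).
LOCUS_GENOTYPES: tuple[str, ...] = ("13", "14", "23", "24")

#: Canonical order of the 16 two-locus genotypes: QTL 1 varies slowest.
TWO_LOCUS_GENOTYPES: tuple[str, ...] = tuple(
    f"{g1}/{g2}" for g1 in LOCUS_GENOTYPES for g2 in LOCUS_GENOTYPES
)

#: The 16 genetic effects, in the fixed order used by every effect vector.
EFFECT_NAMES: tuple[str, ...] = (
    "mu",
    "alpha1", "beta1", "gamma1",
    "alpha2", "beta2", "gamma2",
    "I_aa", "I_ab", "I_ba", "I_bb",
    "J_ag", "J_bg",
    "K_ga", "K_gb",
    "L_gg",
)

EFFECT_INDEX: dict[str, int] = {name: i for i, name in enumerate(EFFECT_NAMES)}

# Single-locus contrast codes over (13, 14, 23, 24):
#   _A scores the P1 allele (1 -> +1, 2 -> -1), _B the P2 allele
#   (3 -> +1, 4 -> -1), _G their product (the dominance contrast).
_ONE = np.ones(4)
_A = np.array([1.0, 1.0, -1.0, -1.0])
_B = np.array([1.0, -1.0, 1.0, -1.0])
_G = _A * _B

# Column recipe of the 16x16 design matrix: (QTL-1 code, QTL-2 code) per
# effect, combined by a Kronecker product (QTL 1 slowest).
_TWO_LOCUS_RECIPE: tuple[tuple[np.ndarray, np.ndarray], ...] = (
    (_ONE, _ONE),           # mu
    (_A, _ONE), (_B, _ONE), (_G, _ONE),     # alpha1, beta1, gamma1
    (_ONE, _A), (_ONE, _B), (_ONE, _G),     # alpha2, beta2, gamma2
    (_A, _A), (_A, _B), (_B, _A), (_B, _B),  # I_aa, I_ab, I_ba, I_bb
    (_A, _G), (_B, _G),     # J_ag, J_bg
    (_G, _A), (_G, _B),     # K_ga, K_gb
    (_G, _G),               # L_gg
)


class EffectContrast(NamedTuple):
    """A +/-1 contrast over the 16 genotypic values testing one effect."""

    effect_name: str
    coefficients: np.ndarray


def single_locus_design_matrix() -> np.ndarray:
    """The 4x4 orthogonal design matrix linking (mu, alpha, beta, gamma)
    to the four genotypic values at one QTL; ``D^-1 = D^T / 4``."""
    return np.column_stack([_ONE, _A, _B, _G])


def two_locus_design_matrix() -> np.ndarray:
    """The 16x16 orthogonal design matrix for the two-QTL decomposition.

    Columns follow :data:`EFFECT_NAMES`; rows follow
    :data:`TWO_LOCUS_GENOTYPES`.  ``D^T D = 16 I`` so ``D^-1 = D^T / 16``.
    """
    return np.column_stack([np.kron(c1, c2) for c1, c2 in _TWO_LOCUS_RECIPE])


_D2 = two_locus_design_matrix()


def _as_effect_vector(a: Iterable[float]) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (16,):
        raise ValueError(f"effect vector must have 16 entries, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("effect vector must be finite")
    return a


def effects_to_genotype_values(a: Iterable[float]) -> np.ndarray:
    """Map a 16-effect vector to the 16 two-locus genotypic values, u = D a."""
    return _D2 @ _as_effect_vector(a)


def genotype_values_to_effects(u: Iterable[float]) -> np.ndarray:
    """Map 16 genotypic values back to effects, a = D^T u / 16."""
    u = np.asarray(u, dtype=float)
    if u.shape != (16,):
        raise ValueError(f"genotypic value table must have 16 entries, got {u.shape}")
    if not np.isfinite(u).all():
        raise ValueError("genotypic values must be finite")
    return _D2.T @ u / 16.0


def effect_contrast(effect_name: str) -> EffectContrast:
    """Contrast vector for ``H0: effect = 0`` on the genotypic values.

    The contrast is the corresponding column of the two-locus design
    matrix: a balanced +/-1 vector (eight +1, eight -1) whose inner product
    with the genotypic-value table is 16 times the effect.
    """
    if effect_name == "mu" or effect_name not in EFFECT_INDEX:
        raise KeyError(
            f"unknown effect {effect_name!r}; expected one of "
            f"{EFFECT_NAMES[1:]}"
        )
    return EffectContrast(effect_name, _D2[:, EFFECT_INDEX[effect_name]].copy())


def genetic_variance(a: Iterable[float]) -> float:
    """Variance of the 16 genotypic values under equal (1/16) frequencies.

    By orthogonality of the design matrix this is the sum of squares of the
    15 non-intercept effects.  Equal frequencies correspond to unlinked (or
    linkage-ignored) QTLs in a full-sib family.
    """
    a = _as_effect_vector(a)
    return float(np.sum(a[1:] ** 2))
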