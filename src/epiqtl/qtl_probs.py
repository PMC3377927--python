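"""Conditional probabilities of two-QTL genotypes given marker genotypes.

Each parental gamete is modelled as a Markov chain of grandparental
origins (0/1) along the loci of a linkage group, with no crossover
interference: the origin flips between consecutive loci with probability
given by Haldane's map function of their distance.  Because the markers of
the cross are fully informative and the parental linkage phases are known,
the observed marker alleles determine the origin of every marker locus,
and the conditional distribution of the origins at one or two putative QTL
positions follows from the chain restricted to the segments that touch the
QTL loci (flanking markers are sufficient by the Markov property).

The 16 two-QTL genotype probabilities (the mixture weights of the
interval-mapping likelihood) are the product of the P1-gamete and
P2-gamete joint origin probabilities, with P1 origins mapped to alleles
{1, 2} and P2 origins to alleles {3, 4}.
"""

from __future__ import annotations

import numpy as np

from .structures import FamilyDataset, LinkageGroup, QtlPosition

__all__ = [
    "haldane_r",
    "interval_qtl_prob",
    "gamete_qtl_origin_probs",
    "gamete_two_qtl_probs",
    "omega_table",
]


def haldane_r(d_cm):
    """Haldane recombination fraction for a map distance in cM.

    r = (1 - exp(-2d/100)) / 2, in [0, 0.5).
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if np.isscalar(d_cm) else r


def interval_qtl_prob(
    left_origin: int, right_origin: int, r1: float, r2: float, r12: float
) -> np.ndarray:
    """Origin distribution of a QTL between two observed flanking markers.

    ``r1``/``r2`` are the recombination fractions from the left/right
    flanking marker to the QTL and ``r12`` between the flanks.  Returns the
    2-vector P(QTL origin = 0), P(QTL origin = 1) under the no-interference
    two-point model, e.g. P(0 | 0, 0) = (1-r1)(1-r2) / (1-r12).
    """
    t1 = np.array([1.0 - r1, r1]) if left_origin == 0 else np.array([r1, 1.0 - r1])
    t2 = np.array([1.0 - r2, r2]) if right_origin == 0 else np.array([r2, 1.0 - r2])
    w = t1 * t2
    total = w.sum()
    if total <= 0.0:
        raise ValueError(
            "impossible flanking configuration (zero recombination across a "
            "recombinant interval)"
        )
    return w / total


def _merge_loci(group: LinkageGroup, qtl_positions: list[float]):
    """Ordered positions of markers plus inserted QTL loci.

    Returns (positions, is_qtl, marker_col, qtl_idx) where ``marker_col``
    maps each merged locus to its marker column (-1 for QTL loci) and
    ``qtl_idx`` to its QTL number (-1 for markers).  A QTL coinciding with
    a marker becomes a separate locus at distance zero.
    """
    for p in qtl_positions:
        if not group.contains(p):
            raise ValueError(
                f"position {p} cM outside the span {group.span} of group "
                f"{group.name!r}"
            )
    pos = list(group.positions)
    kinds = [("M", j) for j in range(len(pos))] + [
        ("Q", k) for k in range(len(qtl_positions))
    ]
    allpos = pos + list(qtl_positions)
    order = sorted(range(len(allpos)), key=lambda i: (allpos[i], kinds[i][0] == "Q"))
    positions = np.array([allpos[i] for i in order])
    marker_col = np.array(
        [kinds[i][1] if kinds[i][0] == "M" else -1 for i in order], dtype=int
    )
    qtl_idx = np.array(
        [kinds[i][1] if kinds[i][0] == "Q" else -1 for i in order], dtype=int
    )
    return positions, marker_col, qtl_idx


def gamete_qtl_origin_probs(
    group: LinkageGroup, marker_origins: np.ndarray, qtl_positions: list[float]
) -> np.ndarray:
    """Joint origin distribution of k QTLs on one group, per gamete.

    ``marker_origins`` is an (n, m) 0/1 matrix of observed marker origins
    for one parent's gametes.  Returns an (n, 2**k) matrix over the origin
    configurations of the QTLs (first QTL slowest); rows sum to 1.  Only
    chain segments adjacent to a QTL locus contribute — the remaining
    transition probabilities are fixed by the observed markers and cancel
    in the normalisation.
    """
    marker_origins = np.atleast_2d(np.asarray(marker_origins, dtype=np.int64))
    k = len(qtl_positions)
    n = marker_origins.shape[0]
    if marker_origins.shape[1] != len(group.markers):
        raise ValueError(
            f"expected {len(group.markers)} marker columns for group "
            f"{group.name!r}, got {marker_origins.shape[1]}"
        )
    positions, marker_col, qtl_idx = _merge_loci(group, qtl_positions)
    seg_r = haldane_r(np.diff(positions))

    n_cfg = 2**k
    weights = np.ones((n, n_cfg))
    # origin of each merged locus under configuration c: markers observed,
    # QTL j takes bit j of c (QTL 0 slowest).
    for s in range(len(positions) - 1):
        ia, ib = s, s + 1
        if qtl_idx[ia] < 0 and qtl_idx[ib] < 0:
            continue  # both markers: constant factor, cancels
        r = seg_r[s]
        for c in range(n_cfg):
            bits = [(c >> (k - 1 - j)) & 1 for j in range(k)]
            oa = (
                marker_origins[:, marker_col[ia]]
                if qtl_idx[ia] < 0
                else np.full(n, bits[qtl_idx[ia]])
            )
            ob = (
                marker_origins[:, marker_col[ib]]
                if qtl_idx[ib] < 0
                else np.full(n, bits[qtl_idx[ib]])
            )
            flip = oa != ob
            weights[:, c] *= np.where(flip, r, 1.0 - r)
    totals = weights.sum(axis=1)
    if np.any(totals <= 0.0):
        raise ValueError("impossible marker/QTL configuration (zero total weight)")
    return weights / totals[:, None]


def gamete_two_qtl_probs(
    marker_origins: np.ndarray,
    group: LinkageGroup,
    pos1: float,
    pos2: float,
) -> np.ndarray:
    """Joint origin distribution of two QTLs on the same group, one gamete.

    ``marker_origins`` is the 0/1 origin vector of one gamete's markers.
    Returns 4 probabilities over (QTL-1 origin, QTL-2 origin) in the order
    (0,0), (0,1), (1,0), (1,1).
    """
    if not pos1 < pos2:
        raise ValueError("pos1 must be strictly left of pos2")
    out = gamete_qtl_origin_probs(group, np.asarray(marker_origins)[None, :], [pos1, pos2])
    return out[0]


def _parent_pair_probs(
    dataset: FamilyDataset, parent: int, pos1: QtlPosition, pos2: QtlPosition
) -> np.ndarray:
    """(n, 4) joint origin probabilities of both QTLs for one parent's gametes."""
    lm = dataset.linkage_map
    if pos1.group == pos2.group:
        origins = dataset.marker_origins(pos1.group)[parent]
        if pos1.position_cm == pos2.position_cm:
            raise ValueError("the two QTL positions must differ")
        p1, p2 = sorted([pos1.position_cm, pos2.position_cm])
        probs = gamete_qtl_origin_probs(lm.group(pos1.group), origins, [p1, p2])
        if pos1.position_cm > pos2.position_cm:  # restore caller's QTL order
            probs = probs[:, [0, 2, 1, 3]]
        return probs
    o1 = dataset.marker_origins(pos1.group)[parent]
    o2 = dataset.marker_origins(pos2.group)[parent]
    a = gamete_qtl_origin_probs(lm.group(pos1.group), o1, [pos1.position_cm])
    b = gamete_qtl_origin_probs(lm.group(pos2.group), o2, [pos2.position_cm])
    return np.einsum("ni,nj->nij", a, b).reshape(-1, 4)


def omega_table(
    dataset: FamilyDataset, pos1: QtlPosition, pos2: QtlPosition
) -> np.ndarray:
    """Mixture weights: (n, 16) conditional two-QTL genotype probabilities.

    Row order follows the offspring of ``dataset``; column order follows
    the canonical 16 two-locus genotypes (13/13, 13/14, ..., 24/24).  Each
    row sums to 1.
    """
    p1 = _parent_pair_probs(dataset, 0, pos1, pos2).reshape(-1, 2, 2)
    p2 = _parent_pair_probs(dataset, 1, pos1, pos2).reshape(-1, 2, 2)
    # genotype (u1 v1 / u2 v2): P1 contributes (u1, u2), P2 contributes (v1, v2)
    omega = np.einsum("nac,nbd->nabcd", p1, p2).reshape(-1, 16)
    return np.ascontiguousarray(omega)
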