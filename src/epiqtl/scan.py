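"""Two-dimensional genome scan for a pair of interacting QTLs.

The scan evaluates the 16-component mixture likelihood on a grid of
position pairs, compares each fit against the no-QTL single-normal null
with a likelihood-ratio statistic LR = 2 (lnL1 - lnL0), and locates the
pair of positions maximising the LR surface.  Significance thresholds
come from phenotype permutations (group-pair-wide, phenotypes shuffled
against fixed marker data).  At the best positions, each of the 15
genetic effects is tested by refitting the mixture under the single
linear constraint that sets the effect to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import em_mapper
from .em_mapper import EmFit
from .genetic_model import (
    EFFECT_NAMES,
    effect_contrast,
    genotype_values_to_effects,
)
from .qtl_probs import gamete_qtl_origin_probs, omega_table
from .structures import FamilyDataset, LinkageGroup, QtlPosition

__all__ = [
    "LrSurface",
    "PermutationResult",
    "lr_statistic",
    "scan_pair",
    "permutation_threshold",
    "effect_tests",
    "effect_test_threshold",
]


@dataclass
class LrSurface:
    """LR values over a grid of QTL position pairs, plus the argmax."""

    group1: str
    group2: str
    grid1: np.ndarray  # positions (cM) on group1
    grid2: np.ndarray
    lr: np.ndarray  # (len(grid1), len(grid2)); NaN where the pair is not scanned
    best: tuple[QtlPosition, QtlPosition, float]
    best_fit: EmFit
    null_loglik: float
    n_nonconverged: int

    def to_frame(self) -> pd.DataFrame:
        """Dense LR matrix as a DataFrame (rows: grid1, columns: grid2)."""
        return pd.DataFrame(self.lr, index=self.grid1, columns=self.grid2)


@dataclass
class PermutationResult:
    """Empirical null of the scan-wide maximum LR."""

    n_perm: int
    alpha: float
    max_lr_draws: np.ndarray
    threshold: float


def lr_statistic(full: EmFit, null_loglik: float) -> float:
    """LR = 2 (loglik_full - loglik_null); tiny negative values clip to 0."""
    lr = 2.0 * (full.loglik - float(null_loglik))
    if -1e-6 < lr < 0.0:
        return 0.0
    return lr


def _grid_positions(group: LinkageGroup, step_cm: float) -> np.ndarray:
    lo, hi = group.span
    grid = np.arange(lo, hi + 1e-9, step_cm)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    return grid


def _interval_index(group: LinkageGroup, pos: float) -> int:
    """Marker interval containing ``pos``; a marker belongs to the interval
    on its right (the last marker to the last interval)."""
    i = int(np.searchsorted(group.positions, pos + 1e-12, side="right")) - 1
    return min(i, len(group.positions) - 2)


class _GridPlan:
    """Precomputed mixture weights for every scanned position pair.

    Built once per dataset/grid; permutations reuse it with shuffled
    phenotypes, so only the EM fits are repeated.
    """

    def __init__(
        self, dataset: FamilyDataset, group1: str, group2: str, step_cm: float
    ):
        lm = dataset.linkage_map
        g1, g2 = lm.group(group1), lm.group(group2)
        self.group1, self.group2 = group1, group2
        self.grid1 = _grid_positions(g1, step_cm)
        self.grid2 = _grid_positions(g2, step_cm)
        self.same_group = group1 == group2

        def singles(group: LinkageGroup, grid: np.ndarray):
            o1, o2 = dataset.marker_origins(group.name)
            return [
                (
                    gamete_qtl_origin_probs(group, o1, [p]),
                    gamete_qtl_origin_probs(group, o2, [p]),
                )
                for p in grid
            ]

        s1 = singles(g1, self.grid1)
        s2 = s1 if self.same_group else singles(g2, self.grid2)

        self.pairs: list[tuple[int, int]] = []
        for i, p1 in enumerate(self.grid1):
            for j, p2 in enumerate(self.grid2):
                if self.same_group:
                    # restrict to distinct marker intervals (pos1 < pos2):
                    # within-interval pairs are weakly identified from
                    # flanking markers only
                    if not (
                        p1 < p2
                        and _interval_index(g1, p1) != _interval_index(g2, p2)
                    ):
                        continue
                self.pairs.append((i, j))

        # joint weights: QTLs on different groups, or in different marker
        # intervals of the same group, are conditionally independent given
        # the observed markers (Markov property of the gamete chain)
        self.omegas: list[np.ndarray] = []
        for i, j in self.pairs:
            a1, a2 = s1[i]
            b1, b2 = s2[j]
            p1pair = np.einsum("na,nb->nab", a1, b1)  # P1 gamete, (q1, q2)
            p2pair = np.einsum("na,nb->nab", a2, b2)
            omega = np.einsum("nac,nbd->nabcd", p1pair, p2pair).reshape(-1, 16)
            self.omegas.append(np.ascontiguousarray(omega))

        if not self.pairs:
            raise ValueError(
                f"empty scan grid for groups {group1!r}/{group2!r} at step "
                f"{step_cm} cM"
            )

    def scan(self, y: np.ndarray, tol: float, max_iter: int) -> LrSurface:
        _, _, ll0 = em_mapper.fit_null_single_mean(y)
        lr = np.full((self.grid1.size, self.grid2.size), np.nan)
        best_val = -np.inf
        best_ij: tuple[int, int] = self.pairs[0]
        best_fit: Optional[EmFit] = None
        n_nonconv = 0
        for (i, j), omega in zip(self.pairs, self.omegas):
            f = em_mapper.fit(omega, y, tol=tol, max_iter=max_iter)
            if not f.converged:
                n_nonconv += 1
            val = lr_statistic(f, ll0)
            lr[i, j] = val
            # ties resolve to the lexicographically smallest position pair,
            # which the row-major loop visits first
            if val > best_val:
                best_val = val
                best_ij = (i, j)
                best_fit = f
        assert best_fit is not None
        bi, bj = best_ij
        best = (
            QtlPosition(self.group1, float(self.grid1[bi])),
            QtlPosition(self.group2, float(self.grid2[bj])),
            best_val,
        )
        best_fit.positions = (best[0], best[1])
        return LrSurface(
            group1=self.group1,
            group2=self.group2,
            grid1=self.grid1,
            grid2=self.grid2,
            lr=lr,
            best=best,
            best_fit=best_fit,
            null_loglik=ll0,
            n_nonconverged=n_nonconv,
        )


def scan_pair(
    dataset: FamilyDataset,
    group1: str,
    group2: str,
    step_cm: float = 2.0,
    em_tol: float = em_mapper.DEFAULT_TOL,
    em_max_iter: int = em_mapper.DEFAULT_MAX_ITER,
) -> LrSurface:
    """Grid scan of a group pair for two interacting QTLs.

    When ``group1 == group2``, only pairs with ``pos1 < pos2`` lying in
    distinct marker intervals are evaluated.  Ties at the maximum resolve
    to the lexicographically smallest position pair.
    """
    plan = _GridPlan(dataset, group1, group2, step_cm)
    return plan.scan(dataset.phenotypes, em_tol, em_max_iter)


def permutation_threshold(
    dataset: FamilyDataset,
    group1: str,
    group2: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    step_cm: float = 2.0,
    seed: Optional[int] = None,
    em_tol: float = em_mapper.DEFAULT_TOL,
    em_max_iter: int = em_mapper.DEFAULT_MAX_ITER,
) -> PermutationResult:
    """Group-pair-wide LR threshold from phenotype permutations.

    Phenotypes are shuffled against the fixed marker data; each
    permutation is rescanned in full and its maximum LR recorded.  The
    threshold is the empirical (1 - alpha) quantile, taken as the
    ceil((1 - alpha) n_perm)-th order statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if n_perm * alpha < 1.0:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve alpha={alpha}; the threshold "
            "is the maximum permutation draw",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    plan = _GridPlan(dataset, group1, group2, step_cm)
    draws = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(dataset.phenotypes)
        draws[b] = plan.scan(y_perm, em_tol, em_max_iter).best[2]
    order = np.sort(draws)
    k = min(int(np.ceil((1.0 - alpha) * n_perm)), n_perm)
    return PermutationResult(
        n_perm=n_perm, alpha=alpha, max_lr_draws=draws, threshold=float(order[k - 1])
    )


def effect_tests(
    dataset: FamilyDataset,
    pos1: QtlPosition,
    pos2: QtlPosition,
    omega: Optional[np.ndarray] = None,
    full: Optional[EmFit] = None,
    em_tol: float = em_mapper.DEFAULT_TOL,
    em_max_iter: int = em_mapper.DEFAULT_MAX_ITER,
) -> pd.DataFrame:
    """Likelihood-ratio tests of the 15 genetic effects at fixed positions.

    For each non-intercept effect the mixture is refitted under the
    constraint that zeroes it; the report lists the constrained
    log-likelihood and LR_effect = 2 (loglik_full - loglik_constrained).
    Decision thresholds are left to the caller (see
    :func:`effect_test_threshold`).
    """
    y = dataset.phenotypes
    if omega is None:
        omega = omega_table(dataset, pos1, pos2)
    if full is None:
        full = em_mapper.fit(
            omega, y, tol=em_tol, max_iter=em_max_iter, positions=(pos1, pos2)
        )
    constrained_fits = {
        name: em_mapper.fit(
            omega, y, constraint=effect_contrast(name), tol=em_tol,
            max_iter=em_max_iter,
        )
        for name in EFFECT_NAMES[1:]
    }
    # The models are nested, so every constrained solution is a feasible
    # start for the full model; if one outscores the full fit (a local
    # maximum), restart the full EM there before forming any LR.
    for con in constrained_fits.values():
        if con.loglik > full.loglik:
            refit = em_mapper.fit(
                omega, y, tol=em_tol, max_iter=em_max_iter,
                init=(con.genotype_values, con.sigma2),
                positions=full.positions,
            )
            if refit.loglik > full.loglik:
                full = refit
    estimates = genotype_values_to_effects(full.genotype_values)
    rows = []
    for name, constrained in constrained_fits.items():
        lr = 2.0 * (full.loglik - constrained.loglik)
        if -1e-6 < lr < 0.0:
            lr = 0.0
        rows.append(
            {
                "effect": name,
                "estimate": estimates[EFFECT_NAMES.index(name)],
                "loglik_full": full.loglik,
                "loglik_constrained": constrained.loglik,
                "lr": lr,
                "converged": constrained.converged,
            }
        )
    report = pd.DataFrame(rows).set_index("effect")
    report.attrs["full_fit"] = full
    return report


def effect_test_threshold(
    omega: np.ndarray,
    constrained_fit: EmFit,
    effect_name: str,
    n_sim: int = 200,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    em_tol: float = em_mapper.DEFAULT_TOL,
    em_max_iter: int = em_mapper.DEFAULT_MAX_ITER,
) -> PermutationResult:
    """Parametric-bootstrap threshold for one effect test.

    Simulates phenotypes from the constrained (null) MLE — genotype drawn
    per offspring from its omega row, residual N(0, sigma2) — and records
    the effect's LR on each simulated dataset.
    """
    rng = np.random.default_rng(seed)
    n = omega.shape[0]
    u = constrained_fit.genotype_values
    sd = float(np.sqrt(constrained_fit.sigma2))
    contrast = effect_contrast(effect_name)
    cum = np.cumsum(omega, axis=1)
    draws = np.empty(n_sim)
    for b in range(n_sim):
        g = (rng.random(n)[:, None] < cum).argmax(axis=1)
        y_sim = u[g] + rng.normal(0.0, sd, size=n)
        f_full = em_mapper.fit(omega, y_sim, tol=em_tol, max_iter=em_max_iter)
        f_con = em_mapper.fit(
            omega, y_sim, constraint=contrast, tol=em_tol, max_iter=em_max_iter
        )
        draws[b] = max(2.0 * (f_full.loglik - f_con.loglik), 0.0)
    order = np.sort(draws)
    k = min(int(np.ceil((1.0 - alpha) * n_sim)), n_sim)
    return PermutationResult(
        n_perm=n_sim, alpha=alpha, max_lr_draws=draws, threshold=float(order[k - 1])
    )
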