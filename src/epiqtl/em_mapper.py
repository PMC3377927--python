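"""EM fitting of the 16-component normal mixture at fixed QTL positions.

The trait model is a finite mixture: offspring ``i`` has phenotype
``y_i ~ N(u_g, sigma^2)`` where ``g`` is its (unobserved) two-locus QTL
genotype and the mixture weights are the marker-conditional genotype
probabilities ``omega_{g|i}``.  The E-step computes genotype posteriors;
the M-step has closed forms — posterior-weighted class means and the
1/n (maximum-likelihood) residual variance.  A single linear constraint
``c^T u = 0`` (one genetic effect set to zero) is handled exactly inside
the M-step by a Lagrange multiplier on the weighted-least-squares
problem, which maximises the EM Q-function under the constraint.

The iteration core is compiled with numba; the module-level
:func:`e_step`, :func:`m_step`, :func:`constrained_m_step` and
:func:`log_likelihood` are plain-numpy building blocks with the same
semantics, usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .genetic_model import EffectContrast
from .structures import QtlPosition

__all__ = [
    "EmFit",
    "log_likelihood",
    "e_step",
    "m_step",
    "constrained_m_step",
    "fit",
    "fit_null_single_mean",
]

#: default convergence tolerance on the log-likelihood increment
DEFAULT_TOL = 1e-8
#: default iteration cap
DEFAULT_MAX_ITER = 2000
#: posterior mass below which a genotype class is frozen for one iteration
DEFAULT_MIN_CLASS_MASS = 1e-10

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class EmFit:
    """Result of one EM fit at fixed QTL positions."""

    genotype_values: np.ndarray  # 16 fitted class means
    sigma2: float
    loglik: float
    posteriors: np.ndarray  # (n, 16)
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    positions: Optional[tuple[QtlPosition, QtlPosition]] = None
    constraint: Optional[EffectContrast] = None

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]


def _check_inputs(omega: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    omega = np.ascontiguousarray(omega, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if omega.ndim != 2 or omega.shape[1] != 16:
        raise ValueError(f"omega must be (n, 16), got {omega.shape}")
    if y.shape != (omega.shape[0],):
        raise ValueError("phenotype vector length must match omega rows")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    if np.any(omega.sum(axis=1) <= 0.0):
        raise ValueError("every omega row must have positive total mass")
    return omega, y


def log_likelihood(omega: np.ndarray, u: np.ndarray, sigma2: float, y: np.ndarray) -> float:
    """Mixture log-likelihood sum_i log sum_g omega_{g|i} phi(y_i; u_g, sigma2)."""
    omega, y = _check_inputs(omega, y)
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    u = np.asarray(u, dtype=float)
    logphi = (
        -0.5 * (_LOG_2PI + np.log(sigma2))
        - 0.5 * (y[:, None] - u[None, :]) ** 2 / sigma2
    )
    with np.errstate(divide="ignore"):
        terms = np.where(omega > 0.0, np.log(np.where(omega > 0.0, omega, 1.0)) + logphi, -np.inf)
    return float(np.sum(logsumexp(terms, axis=1)))


def e_step(omega: np.ndarray, u: np.ndarray, sigma2: float, y: np.ndarray) -> np.ndarray:
    """Posterior genotype probabilities, computed stably in log space."""
    omega, y = _check_inputs(omega, y)
    if sigma2 <= 0.0:
        raise ValueError("sigma2 must be positive")
    u = np.asarray(u, dtype=float)
    logw = -0.5 * (y[:, None] - u[None, :]) ** 2 / sigma2
    logw -= logw.max(axis=1, keepdims=True)
    w = omega * np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def m_step(
    posteriors: np.ndarray,
    y: np.ndarray,
    prev_u: Optional[np.ndarray] = None,
    min_class_mass: float = DEFAULT_MIN_CLASS_MASS,
) -> tuple[np.ndarray, float]:
    """Closed-form M-step: weighted class means and ML residual variance.

    A class whose posterior mass falls below ``min_class_mass`` keeps its
    previous mean (``prev_u``; the overall mean if none is supplied), since
    its weighted-mean update is 0/0.
    """
    pi = np.asarray(posteriors, dtype=float)
    y = np.asarray(y, dtype=float)
    mass = pi.sum(axis=0)
    fallback = np.full(16, y.mean()) if prev_u is None else np.asarray(prev_u, float)
    ok = mass >= min_class_mass
    u = np.where(ok, (pi * y[:, None]).sum(axis=0) / np.where(ok, mass, 1.0), fallback)
    sigma2 = float(np.sum(pi * (y[:, None] - u[None, :]) ** 2) / y.size)
    return u, sigma2


def constrained_m_step(
    posteriors: np.ndarray,
    y: np.ndarray,
    contrast: EffectContrast,
    prev_u: Optional[np.ndarray] = None,
    min_class_mass: float = DEFAULT_MIN_CLASS_MASS,
) -> tuple[np.ndarray, float]:
    """M-step maximising the Q-function subject to ``c^T u = 0``.

    With class masses n_g and unconstrained weighted means ybar_g, the
    constrained optimum is ``u_g = ybar_g - lambda c_g / n_g`` with
    ``lambda = (sum_g c_g ybar_g) / (sum_g c_g^2 / n_g)``.  Classes below
    ``min_class_mass`` are frozen at their previous value and contribute a
    constant offset to the constraint.
    """
    pi = np.asarray(posteriors, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(contrast.coefficients, dtype=float)
    mass = pi.sum(axis=0)
    fallback = np.full(16, y.mean()) if prev_u is None else np.asarray(prev_u, float)
    ok = mass >= min_class_mass
    ybar = np.where(ok, (pi * y[:, None]).sum(axis=0) / np.where(ok, mass, 1.0), fallback)
    frozen_offset = float(np.sum(c[~ok] * ybar[~ok]))
    den = float(np.sum(c[ok] ** 2 / mass[ok]))
    lam = (float(np.sum(c[ok] * ybar[ok])) + frozen_offset) / den if den > 0 else 0.0
    u = ybar.copy()
    u[ok] = ybar[ok] - lam * c[ok] / mass[ok]
    sigma2 = float(np.sum(pi * (y[:, None] - u[None, :]) ** 2) / y.size)
    return u, sigma2


@njit(cache=True)
def _em_core(omega, y, u0, s0, c, constrained, tol, max_iter, min_mass):  # pragma: no cover
    n = y.shape[0]
    u = u0.copy()
    s2 = s0
    post = np.empty((n, 16))
    trace = np.empty(max_iter + 1)
    tmp = np.empty(16)
    prev_ll = -np.inf
    converged = False
    n_trace = 0
    for it in range(max_iter + 1):
        # E-step and log-likelihood at the current parameters
        inv2 = 0.5 / s2
        logc = -0.5 * (_LOG_2PI + np.log(s2))
        ll = 0.0
        for i in range(n):
            mx = -np.inf
            for g in range(16):
                d = y[i] - u[g]
                tmp[g] = -d * d * inv2
                if omega[i, g] > 0.0 and tmp[g] > mx:
                    mx = tmp[g]
            tot = 0.0
            for g in range(16):
                w = omega[i, g] * np.exp(tmp[g] - mx)
                post[i, g] = w
                tot += w
            for g in range(16):
                post[i, g] /= tot
            ll += np.log(tot) + mx + logc
        trace[it] = ll
        n_trace = it + 1
        if it > 0 and abs(ll - prev_ll) < tol:
            converged = True
            break
        if it == max_iter:
            break
        prev_ll = ll
        # M-step
        mass = np.zeros(16)
        ysum = np.zeros(16)
        for i in range(n):
            for g in range(16):
                mass[g] += post[i, g]
                ysum[g] += post[i, g] * y[i]
        ybar = np.empty(16)
        for g in range(16):
            ybar[g] = ysum[g] / mass[g] if mass[g] >= min_mass else u[g]
        if constrained:
            num = 0.0
            den = 0.0
            for g in range(16):
                if mass[g] >= min_mass:
                    num += c[g] * ybar[g]
                    den += c[g] * c[g] / mass[g]
                else:
                    num += c[g] * ybar[g]  # frozen offset
            lam = num / den if den > 0.0 else 0.0
            for g in range(16):
                if mass[g] >= min_mass:
                    u[g] = ybar[g] - lam * c[g] / mass[g]
                else:
                    u[g] = ybar[g]
        else:
            for g in range(16):
                u[g] = ybar[g]
        acc = 0.0
        for i in range(n):
            for g in range(16):
                d = y[i] - u[g]
                acc += post[i, g] * d * d
        s2 = acc / n
        if s2 < 1e-12:
            s2 = 1e-12
    return u, s2, post, trace[:n_trace], converged


def initial_values(omega: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic starting point: omega-weighted class means of y and the
    total phenotypic variance."""
    mass = omega.sum(axis=0)
    ok = mass > 0.0
    u0 = np.full(16, y.mean())
    u0[ok] = (omega[:, ok] * y[:, None]).sum(axis=0) / mass[ok]
    s0 = float(np.var(y))
    return u0, max(s0, 1e-12)


def fit(
    omega: np.ndarray,
    y: np.ndarray,
    constraint: Optional[EffectContrast] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    min_class_mass: float = DEFAULT_MIN_CLASS_MASS,
    init: Optional[tuple[np.ndarray, float]] = None,
    positions: Optional[tuple[QtlPosition, QtlPosition]] = None,
    n_starts: int = 1,
    start_seed: Optional[int] = None,
) -> EmFit:
    """Run EM to convergence at fixed QTL positions.

    ``constraint``, when given, forces ``c^T u = 0`` throughout (the null
    model of the corresponding effect test).  The default start is
    deterministic (omega-weighted class means, total variance);
    ``init=(u0, sigma2_0)`` overrides it, and ``n_starts > 1`` adds random
    restarts (class means resampled from the phenotypes) and keeps the
    best final log-likelihood.
    """
    omega, y = _check_inputs(omega, y)
    if init is None:
        u0, s0 = initial_values(omega, y)
    else:
        u0, s0 = np.asarray(init[0], dtype=float).copy(), float(init[1])
    c = np.zeros(16) if constraint is None else np.asarray(constraint.coefficients, float)
    starts: list[tuple[np.ndarray, float]] = [(u0, s0)]
    if n_starts > 1:
        rng = np.random.default_rng(start_seed)
        for _ in range(n_starts - 1):
            starts.append(
                (rng.choice(y, size=16, replace=True).astype(float),
                 max(float(np.var(y)) / 2.0, 1e-12))
            )
    best: Optional[EmFit] = None
    for u_start, s_start in starts:
        if constraint is not None:
            # project the start onto the constraint so every iterate satisfies it
            u_start = u_start - c * (c @ u_start) / (c @ c)
        u, s2, post, trace, converged = _em_core(
            omega, y, u_start.copy(), s_start, c, constraint is not None,
            tol, max_iter, min_class_mass,
        )
        candidate = EmFit(
            genotype_values=u,
            sigma2=float(s2),
            loglik=float(trace[-1]),
            posteriors=post,
            n_iter=len(trace) - 1,
            converged=bool(converged),
            loglik_trace=trace,
            positions=positions,
            constraint=constraint,
        )
        if best is None or candidate.loglik > best.loglik:
            best = candidate
    assert best is not None
    return best


def fit_null_single_mean(y: np.ndarray) -> tuple[float, float, float]:
    """MLEs and log-likelihood of the no-QTL model (one normal component).

    Returns (mean, ML variance with the 1/n divisor, log-likelihood).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    mu = float(y.mean())
    sigma2 = float(np.var(y))
    if sigma2 <= 0.0:
        raise ValueError("degenerate phenotypes: zero variance")
    loglik = -0.5 * y.size * (_LOG_2PI + np.log(sigma2) + 1.0)
    return mu, sigma2, loglik
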