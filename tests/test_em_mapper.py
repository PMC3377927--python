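"""EM building blocks and full fits against independent oracles."""

import numpy as np
import pytest
from scipy import optimize, stats

from epiqtl import em_mapper
from epiqtl.em_mapper import (
    constrained_m_step,
    e_step,
    fit,
    fit_null_single_mean,
    log_likelihood,
    m_step,
)
from epiqtl.genetic_model import effect_contrast


def random_instance(rng, n=60, informative=True):
    """A small mixture instance with valid omega rows."""
    if informative:
        omega = rng.dirichlet(np.full(16, 0.3), size=n)
    else:
        omega = np.full((n, 16), 1 / 16)
    u = rng.normal(0, 5, size=16)
    g = np.array([rng.choice(16, p=w) for w in omega])
    y = u[g] + rng.normal(0, 2.0, size=n)
    return omega, y


def naive_loglik(omega, u, sigma2, y):
    """Direct double-loop evaluation of the mixture likelihood."""
    total = 0.0
    for i in range(len(y)):
        mix = sum(
            omega[i, g] * stats.norm.pdf(y[i], u[g], np.sqrt(sigma2))
            for g in range(16)
        )
        total += np.log(mix)
    return total


def q_function(posteriors, omega, u, sigma2, y):
    """EM Q-function: expected complete-data log-likelihood."""
    logf = stats.norm.logpdf(y[:, None], u[None, :], np.sqrt(sigma2))
    with np.errstate(divide="ignore"):
        logw = np.where(omega > 0, np.log(np.where(omega > 0, omega, 1)), -np.inf)
    terms = posteriors * (logw + logf)
    return float(np.sum(np.where(posteriors > 0, terms, 0.0)))


class TestLogLikelihood:
    def test_matches_direct_summation(self, rng):
        omega, y = random_instance(rng)
        u = rng.normal(0, 5, size=16)
        assert log_likelihood(omega, u, 3.0, y) == pytest.approx(
            naive_loglik(omega, u, 3.0, y), abs=1e-10
        )

    def test_degenerate_mixture_is_plain_normal(self, rng):
        y = rng.normal(2.0, 1.0, size=40)
        omega = np.zeros((40, 16))
        omega[:, 5] = 1.0
        u = np.full(16, y.mean())
        expected = stats.norm.logpdf(y, y.mean(), np.sqrt(2.0)).sum()
        assert log_likelihood(omega, u, 2.0, y) == pytest.approx(expected)

    def test_equal_means_ignore_omega(self, rng):
        omega, y = random_instance(rng)
        u = np.full(16, 1.0)
        alt = np.full((len(y), 16), 1 / 16)
        assert log_likelihood(omega, u, 2.5, y) == pytest.approx(
            log_likelihood(alt, u, 2.5, y)
        )

    def test_invalid_sigma2(self, rng):
        omega, y = random_instance(rng)
        with pytest.raises(ValueError):
            log_likelihood(omega, np.zeros(16), 0.0, y)


class TestESTep:
    def test_uniform_case(self):
        y = np.array([1.0, -2.0])
        post = e_step(np.full((2, 16), 1 / 16), np.zeros(16), 1.0, y)
        assert np.allclose(post, 1 / 16)

    def test_degenerate_omega(self, rng):
        omega = np.zeros((5, 16))
        omega[:, 3] = 1.0
        post = e_step(omega, rng.normal(size=16), 1.0, rng.normal(size=5))
        assert np.allclose(post[:, 3], 1.0)

    def test_extreme_values_stay_normalised(self, rng):
        omega, _ = random_instance(rng)
        y = np.full(60, 1e6)
        post = e_step(omega, np.linspace(-5, 5, 16), 0.01, y)
        assert np.all(np.isfinite(post))
        assert np.allclose(post.sum(axis=1), 1.0)


class TestMStep:
    def test_hard_posteriors_give_class_means(self, rng):
        y = rng.normal(size=64)
        g = np.repeat(np.arange(16), 4)
        post = np.zeros((64, 16))
        post[np.arange(64), g] = 1.0
        u, s2 = m_step(post, y)
        for k in range(16):
            assert u[k] == pytest.approx(y[g == k].mean())
        pooled = sum(((y[g == k] - u[k]) ** 2).sum() for k in range(16)) / 64
        assert s2 == pytest.approx(pooled)

    def test_uniform_posteriors_collapse_to_grand_mean(self, rng):
        y = rng.normal(size=30)
        u, _ = m_step(np.full((30, 16), 1 / 16), y)
        assert np.allclose(u, y.mean())

    def test_increases_q_function(self, rng):
        omega, y = random_instance(rng)
        u_old = rng.normal(0, 5, size=16)
        s_old = 4.0
        post = e_step(omega, u_old, s_old, y)
        u_new, s_new = m_step(post, y)
        assert q_function(post, omega, u_new, s_new, y) >= q_function(
            post, omega, u_old, s_old, y
        )

    def test_empty_class_frozen(self, rng):
        post = np.zeros((10, 16))
        post[:, 0] = 1.0
        prev = np.arange(16.0)
        u, _ = m_step(post, rng.normal(size=10), prev_u=prev)
        assert np.array_equal(u[1:], prev[1:])


class TestConstrainedMStep:
    def test_constraint_satisfied(self, rng):
        omega, y = random_instance(rng)
        post = e_step(omega, rng.normal(size=16), 2.0, y)
        for name in ("alpha1", "L_gg", "J_bg"):
            u, _ = constrained_m_step(post, y, effect_contrast(name))
            c = effect_contrast(name).coefficients
            assert abs(c @ u) < 1e-10 * max(1.0, np.abs(u).max())

    def test_already_satisfied_is_noop(self, rng):
        y = np.concatenate([rng.normal(size=32)] * 2)
        g = np.tile(np.repeat(np.arange(16), 2), 2)
        post = np.zeros((64, 16))
        post[np.arange(64), g] = 1.0
        c = effect_contrast("alpha1")
        u_unc, _ = m_step(post, y)
        # symmetrise the data so the unconstrained means satisfy the contrast
        u_sym = u_unc - c.coefficients * (c.coefficients @ u_unc) / 16
        y_sym = u_sym[g]
        post_sym = post
        u_con, _ = constrained_m_step(post_sym, y_sym, c)
        u_ref, _ = m_step(post_sym, y_sym)
        assert np.allclose(u_con, u_ref)

    def test_equal_masses_closed_form(self, rng):
        y = rng.normal(size=32)
        g = np.repeat(np.arange(16), 2)
        post = np.zeros((32, 16))
        post[np.arange(32), g] = 1.0
        c = effect_contrast("gamma1").coefficients
        ybar, _ = m_step(post, y)
        u, _ = constrained_m_step(post, y, effect_contrast("gamma1"))
        assert np.allclose(u, ybar - c * (c @ ybar) / 16)

    def test_beats_any_other_feasible_point(self, rng):
        """The Lagrange solution minimises the weighted SSE on the
        constraint plane (checked against scipy SLSQP)."""
        omega, y = random_instance(rng)
        post = e_step(omega, rng.normal(size=16), 2.0, y)
        mass = post.sum(axis=0)
        ybar = (post * y[:, None]).sum(axis=0) / mass
        c = effect_contrast("I_ab").coefficients

        res = optimize.minimize(
            lambda u: mass @ (ybar - u) ** 2,
            x0=ybar - c * (c @ ybar) / 16,
            constraints={"type": "eq", "fun": lambda u: c @ u},
            method="SLSQP",
        )
        u, _ = constrained_m_step(post, y, effect_contrast("I_ab"))
        assert mass @ (ybar - u) ** 2 <= res.fun + 1e-8


class TestFit:
    def test_loglik_monotone_on_random_instances(self):
        rng = np.random.default_rng(123)
        for k in range(50):
            omega, y = random_instance(rng, n=40, informative=(k % 2 == 0))
            f = fit(omega, y, tol=1e-10, max_iter=300)
            assert np.all(np.diff(f.loglik_trace) >= -1e-8)

    def test_constrained_never_beats_unconstrained(self):
        from epiqtl.qtl_probs import omega_table
        from epiqtl.simulator import benchmark_design, simulate_family
        from epiqtl.structures import QtlPosition

        ds = simulate_family(benchmark_design(200, 0.4, seed=31))
        omega = omega_table(ds, QtlPosition("LG1", 28.0), QtlPosition("LG1", 72.0))
        y = ds.phenotypes
        full = fit(omega, y)
        for name in ("alpha1", "gamma2", "I_bb", "L_gg"):
            con = fit(omega, y, constraint=effect_contrast(name))
            assert con.loglik <= full.loglik + 1e-8
            c = effect_contrast(name).coefficients
            scale = max(1.0, np.abs(con.genotype_values).max())
            assert abs(c @ con.genotype_values) <= 1e-8 * scale

    def test_hard_assignment_recovers_class_means(self, rng):
        u_true = np.linspace(-30, 30, 16)
        g = np.repeat(np.arange(16), 5)
        y = u_true[g] + rng.normal(0, 1e-4, size=80)
        omega = np.zeros((80, 16))
        omega[np.arange(80), g] = 1.0
        f = fit(omega, y)
        for k in range(16):
            assert f.genotype_values[k] == pytest.approx(y[g == k].mean(), abs=1e-8)

    def test_matches_stepwise_numpy_iteration(self, rng):
        """The compiled core reproduces the plain-numpy E/M alternation."""
        omega, y = random_instance(rng)
        f = fit(omega, y, tol=1e-9, max_iter=500)
        u, s2 = em_mapper.initial_values(omega, y)
        for _ in range(f.n_iter):
            post = e_step(omega, u, s2, y)
            u, s2 = m_step(post, y, prev_u=u)
        assert np.allclose(f.genotype_values, u, atol=1e-6)
        assert f.sigma2 == pytest.approx(s2, rel=1e-6)

    def test_reaches_multistart_optimizer_loglik(self):
        """EM attains the best log-likelihood found by a generic optimizer
        restarted from random points (tiny instance, 17 free parameters)."""
        rng = np.random.default_rng(77)
        omega, y = random_instance(rng, n=48)
        f = fit(omega, y, tol=1e-12, max_iter=5000, n_starts=60, start_seed=5)

        def neg_ll(theta):
            u, log_s2 = theta[:16], theta[16]
            return -log_likelihood(omega, u, np.exp(log_s2), y)

        best = -np.inf
        for _ in range(10):
            x0 = np.concatenate([rng.normal(y.mean(), y.std(), 16), [np.log(y.var())]])
            res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                    options={"maxiter": 2000, "fatol": 1e-10})
            best = max(best, -res.fun)
        assert f.loglik >= best - 1e-6

    def test_rejects_bad_inputs(self, rng):
        omega, y = random_instance(rng)
        with pytest.raises(ValueError):
            fit(omega[:, :8], y)
        bad = omega.copy()
        bad[0] = 0.0
        with pytest.raises(ValueError):
            fit(bad, y)
        with pytest.raises(ValueError):
            fit(omega, np.r_[y[:-1], np.nan])


class TestParameterRecovery:
    def test_effect_mae_at_large_n(self):
        """With positions fixed at the truth and n = 2000, h2 = 0.4, the
        mean absolute error of each effect over replicates stays within
        3x its published between-replicate standard error."""
        from epiqtl.genetic_model import EFFECT_NAMES
        from epiqtl.simulator import BENCHMARK_EFFECTS
        from epiqtl.study import fixed_position_study

        published_se = dict(zip(EFFECT_NAMES, (
            0.51, 0.55, 0.54, 0.58, 0.53, 0.53, 0.60,
            0.61, 0.59, 0.61, 0.60, 0.67, 0.65, 0.67, 0.64, 0.73,
        )))
        df = fixed_position_study(2000, 0.4, n_reps=100, seed=11)
        truth = dict(zip(EFFECT_NAMES, BENCHMARK_EFFECTS))
        for name in EFFECT_NAMES:
            mae = (df[name] - truth[name]).abs().mean()
            assert mae <= 3 * published_se[name], name


class TestNullFit:
    def test_two_point_example(self):
        mu, s2, _ = fit_null_single_mean(np.array([0.0, 2.0]))
        assert mu == 1.0
        assert s2 == 1.0

    def test_matches_mixture_with_equal_means(self, rng):
        y = rng.normal(3.0, 2.0, size=50)
        mu, s2, ll = fit_null_single_mean(y)
        omega = np.full((50, 16), 1 / 16)
        assert ll == pytest.approx(log_likelihood(omega, np.full(16, mu), s2, y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_null_single_mean(np.full(10, 3.3))
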