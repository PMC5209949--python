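"""Negative binomial primitives: log-pmf, derivatives, pseudo-data, theta."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from nbmix import (DomainError, NBParams, compute_pseudo_data,
                   nb_eta_derivatives, nb_log_pmf, nb_moments, update_theta)

# log NB(3 | mu=2, theta=0.5): frozen from a 30-digit symbolic evaluation
LOGPMF_3_2_05 = -2.6373004199653603


class TestLogPmf:
    def test_zero_count_closed_form(self):
        # P(y=0) = (theta/(mu+theta))**theta
        lp = nb_log_pmf([0], NBParams(mu=np.array([1.0]), theta=1.0))
        assert lp[0] == pytest.approx(np.log(0.5), abs=1e-12)

    def test_high_precision_oracle_value(self):
        lp = nb_log_pmf([3], NBParams(mu=np.array([2.0]), theta=0.5))
        assert lp[0] == pytest.approx(LOGPMF_3_2_05, abs=1e-12)

    def test_normalization(self):
        y = np.arange(2001)
        lp = nb_log_pmf(y, NBParams(mu=np.full(2001, 2.0), theta=1.5))
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("y,mu,theta", [
        ([-1], 1.0, 1.0), ([0.5], 1.0, 1.0), ([1], -1.0, 1.0), ([1], 1.0, 0.0),
    ])
    def test_domain_errors(self, y, mu, theta):
        with pytest.raises(DomainError):
            nb_log_pmf(y, NBParams(mu=np.array([mu]), theta=theta))


class TestMoments:
    def test_variance_formula_and_poisson_limit(self):
        m, v = nb_moments(NBParams(mu=np.array([2.0]), theta=1.0))
        assert v[0] == pytest.approx(6.0)
        _, v = nb_moments(NBParams(mu=np.array([3.0]), theta=1e12))
        assert v[0] == pytest.approx(3.0, rel=1e-10)

    def test_monte_carlo_moments(self, rng):
        mu, theta = 5.0, 0.1
        _, v = nb_moments(NBParams(mu=np.array([mu]), theta=theta))
        assert v[0] == pytest.approx(255.0)
        draws = rng.negative_binomial(theta, theta / (theta + mu), size=10**6)
        assert draws.var() == pytest.approx(v[0], rel=0.02)
        assert draws.mean() == pytest.approx(mu, rel=0.02)

    def test_gamma_poisson_mixture_identity(self, rng):
        # NB(mu, theta) == Poisson(mu * eps), eps ~ Gamma(theta, rate=theta)
        mu, theta, n = 3.0, 0.8, 10**6
        eps = rng.gamma(theta, 1.0 / theta, size=n)
        draws = rng.poisson(mu * eps)
        ys = np.arange(15)
        pmf = np.exp(nb_log_pmf(ys, NBParams(mu=np.full(15, mu), theta=theta)))
        emp = np.bincount(draws, minlength=15)[:15] / n
        mc_se = np.sqrt(pmf * (1 - pmf) / n)
        assert np.all(np.abs(emp - pmf) < 5 * mc_se + 1e-9)


def _fd_derivs(y, eta, theta):
    def f(e):
        return nb_log_pmf([y], NBParams(mu=np.array([np.exp(e)]),
                                        theta=theta))[0]
    h1, h2 = 1e-5, 1e-3
    L1 = (f(eta + h1) - f(eta - h1)) / (2 * h1)
    # fourth-order five-point stencil keeps truncation below 1e-9
    L2 = (-f(eta + 2 * h2) + 16 * f(eta + h2) - 30 * f(eta)
          + 16 * f(eta - h2) - f(eta - 2 * h2)) / (12 * h2**2)
    return L1, L2


class TestEtaDerivatives:
    @pytest.mark.parametrize("y", [0, 1, 5, 50])
    @pytest.mark.parametrize("eta", [-3.0, 0.0, 3.0])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 5.0])
    def test_matches_finite_differences(self, y, eta, theta):
        L1, L2 = nb_eta_derivatives([y], [eta], theta)
        fd1, fd2 = _fd_derivs(y, eta, theta)
        assert abs(L1[0] - fd1) <= 1e-6 * max(1.0, abs(fd1))
        assert abs(L2[0] - fd2) <= 1e-6 * max(1.0, abs(fd2))
        assert L2[0] < 0

    def test_score_vanishes_at_mean(self):
        eta = np.array([0.7])
        L1, _ = nb_eta_derivatives([np.exp(0.7).round()], np.log([np.exp(0.7).round()]), 2.0)
        assert L1[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_limit_score(self):
        L1, _ = nb_eta_derivatives([4], [0.0], 1e10)
        assert L1[0] == pytest.approx(3.0, rel=1e-6)

    def test_extreme_eta_is_finite(self):
        L1, L2 = nb_eta_derivatives([0, 7, 100], [-200.0, 0.0, 200.0], 0.5)
        assert np.all(np.isfinite(L1)) and np.all(np.isfinite(L2))
        assert np.all(L2 < 0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(y=st.integers(min_value=0, max_value=10**6),
       eta=st.floats(min_value=-100, max_value=100),
       theta=st.floats(min_value=1e-3, max_value=1e6))
def test_pseudo_weights_positive_and_finite(y, eta, theta):
    pd_ = compute_pseudo_data([y], [eta], theta)
    assert pd_.w[0] > 0 and np.isfinite(pd_.w[0]) and np.isfinite(pd_.t[0])


class TestPseudoData:
    def test_pseudo_response_equals_eta_at_fitted_mean(self):
        eta = np.log(np.array([4.0]))
        for scoring in ("observed", "fisher"):
            pd_ = compute_pseudo_data([4], eta, 2.0, scoring=scoring)
            assert pd_.t[0] == pytest.approx(eta[0], abs=1e-12)

    def test_consistent_with_derivative_oracle(self):
        y, eta, theta = 5, 1.0, 2.0
        fd1, fd2 = _fd_derivs(y, eta, theta)
        pd_ = compute_pseudo_data([y], [eta], theta)
        assert pd_.w[0] == pytest.approx(-fd2, rel=1e-6)
        assert pd_.t[0] == pytest.approx(eta - fd1 / fd2, rel=1e-6)

    def test_fisher_working_data_identity(self):
        # t = eta + (y - mu)/mu and w = mu*theta/(mu+theta)
        y, eta, theta = 7, 1.3, 2.5
        mu = np.exp(eta)
        pd_ = compute_pseudo_data([y], [eta], theta, scoring="fisher")
        assert pd_.w[0] == pytest.approx(mu * theta / (mu + theta), rel=1e-12)
        assert pd_.t[0] == pytest.approx(eta + (y - mu) / mu, rel=1e-12)

    def test_degenerate_zero_count_low_eta(self):
        pd_ = compute_pseudo_data([0], [-20.0], 1.0)
        assert np.isfinite(pd_.t[0]) and pd_.w[0] >= 1e-10


def _grid_golden_theta(y, mu, lo=1e-2, hi=1e4):
    """Independent profile maximizer: dense log-grid + golden refinement."""
    zs = np.linspace(np.log(lo), np.log(hi), 400)
    lls = [np.sum(nb_log_pmf(y, NBParams(mu=mu, theta=np.exp(z)))) for z in zs]
    j = int(np.argmax(lls))
    a, b = zs[max(j - 1, 0)], zs[min(j + 1, len(zs) - 1)]
    res = optimize.minimize_scalar(
        lambda z: -np.sum(nb_log_pmf(y, NBParams(mu=mu, theta=np.exp(z)))),
        bracket=None, bounds=(a, b), method="bounded",
        options={"xatol": 1e-12})
    return float(np.exp(res.x))


class TestUpdateTheta:
    def test_matches_grid_golden_oracle(self):
        r = np.random.default_rng(5)
        n = 5000
        mu = np.exp(r.uniform(0.5, 3.0, n))
        y = r.negative_binomial(1.2, 1.2 / (1.2 + mu))
        th = update_theta(y, mu, theta_init=1.0)
        oracle = _grid_golden_theta(y, mu)
        assert th == pytest.approx(oracle, abs=1e-4)

    def test_poisson_data_hit_upper_clamp(self):
        r = np.random.default_rng(11)
        mu = np.exp(r.uniform(0.5, 2.5, 2000))
        y = r.poisson(mu)
        th = update_theta(y, mu, theta_init=1.0, bounds=(1e-2, 1e4))
        assert th == pytest.approx(1e4, rel=1e-6)

    def test_constant_counts_clamped_high(self):
        y = np.full(50, 4)
        th = update_theta(y, np.full(50, 4.0), theta_init=1.0)
        assert th == pytest.approx(1e4, rel=1e-6)

    def test_likelihood_ascent(self):
        r = np.random.default_rng(3)
        mu = np.exp(r.uniform(0.2, 3.0, 400))
        y = r.negative_binomial(0.6, 0.6 / (0.6 + mu))
        for th0 in (0.05, 1.0, 50.0):
            th = update_theta(y, mu, theta_init=th0)
            ll0 = np.sum(nb_log_pmf(y, NBParams(mu=mu, theta=th0)))
            ll1 = np.sum(nb_log_pmf(y, NBParams(mu=mu, theta=th)))
            assert ll1 >= ll0 - 1e-9
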