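"""Marginalized occupancy likelihood: closed forms, enumeration oracle,
gradient correctness, and structural properties."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, logit

from beeshift.covariates import EraCovariates
from beeshift.histories import DetectionData
from beeshift.likelihood import (
    ModelSpec,
    OccupancyParams,
    SufficientStats,
    linear_predictor,
    make_log_posterior,
    marginal_loglik,
)

from _oracles import brute_force_loglik


def make_detection_data(S, J, K, T, y, visited, range_mask):
    """Assemble a DetectionData from explicit arrays."""
    y = np.asarray(y, dtype=np.int8).reshape(S, J, K, T)
    visited = np.asarray(visited, dtype=bool).reshape(J, K, T)
    range_mask = np.asarray(range_mask, dtype=bool).reshape(S, J)
    observed = visited[None] & range_mask[:, :, None, None]
    y = y & observed
    return DetectionData(
        y=y, observed=observed, visited=visited, range_mask=range_mask,
        record_counts=y.sum(axis=0).astype(np.int64),
        species=[f"sp{i}" for i in range(S)], sites=list(range(J)),
    )


def random_instance(rng, kind):
    """Small random dataset + parameters for oracle comparison."""
    S = rng.integers(1, 4)
    J = rng.integers(1, 3)
    K = rng.integers(2, 3)  # >= 2 so the era index is well defined
    T = rng.integers(1, 4)
    while True:
        visited = rng.random((J, K, T)) < 0.7
        range_mask = rng.random((S, J)) < 0.8
        n_blocks = sum(
            1 for i in range(S) for j in range(J) for k in range(K)
            if range_mask[i, j] and visited[j, k].any()
        )
        if 1 <= n_blocks <= 12:
            break
    y = rng.random((S, J, K, T)) < 0.4
    data = make_detection_data(S, J, K, T, y, visited, range_mask)
    spec = ModelSpec(kind=kind, detection_variant=(
        "site_era_ranef_plus_era_fixed" if rng.random() < 0.3 else "site_era_ranef"
    ))
    params = OccupancyParams(
        alpha=rng.normal(0, 1, S),
        psi_era=rng.normal(0, 1, S),
        psi_temp=rng.normal(0, 1, S),
        psi_temp2=float(rng.normal(0, 0.5)),
        psi_precip=rng.normal(0, 1, S),
        psi_floral=rng.normal(0, 1, S),
        p0=float(rng.normal(0, 1)),
        delta=rng.normal(0, 1, (J, K)),
        p_era=float(rng.normal(0, 0.5)),
    )
    cov = EraCovariates(
        temp=rng.normal(15, 5, (J, K)),
        precip=rng.normal(70, 10, (J, K)),
        floral=rng.uniform(0.8, 1.6, (J, K)),
    ).standardized()
    return data, params, spec, cov


class TestClosedForms:
    """Hand-computable single-history likelihoods."""

    def _one_block(self, history):
        # one species, one site, eras 1..2, era 2 unvisited; slope zero
        # so psi = expit(0) = 0.5 regardless of the era index
        T = len(history)
        y = np.zeros((1, 1, 2, T))
        y[0, 0, 0] = history
        visited = np.zeros((1, 2, T), dtype=bool)
        visited[0, 0] = True
        data = make_detection_data(1, 1, 2, T, y, visited, [[True]])
        params = OccupancyParams(
            alpha=np.zeros(1), psi_era=np.zeros(1), p0=0.0,
            delta=np.zeros((1, 2)),
        )
        return marginal_loglik(data, params, ModelSpec(kind="era"))

    def test_all_zero_history(self):
        # psi = p = 1/2, 4 visited intervals, no detection:
        # L = 0.5 * 0.5^4 + 0.5 = 0.53125
        assert np.exp(self._one_block([0, 0, 0, 0])) == pytest.approx(
            0.53125, abs=1e-12
        )

    def test_single_detection_history(self):
        # occupied branch only: 0.5 * 0.5^4 = 0.03125
        assert np.exp(self._one_block([1, 0, 0, 0])) == pytest.approx(
            0.03125, abs=1e-12
        )

    def test_detection_at_unvisited_interval_asserts(self):
        y = np.zeros((1, 1, 2, 4))
        y[0, 0, 0, 0] = 1
        visited = np.zeros((1, 2, 4), dtype=bool)
        visited[0, 0, 1] = True  # visit elsewhere; y=1 interval unvisited
        data = make_detection_data(1, 1, 2, 4, y, visited, [[True]])
        data.y[0, 0, 0, 0] = 1  # force the corrupt state past the constructor
        params = OccupancyParams(
            alpha=np.zeros(1), psi_era=np.zeros(1), p0=0.0, delta=np.zeros((1, 2))
        )
        with pytest.raises(AssertionError):
            marginal_loglik(data, params, ModelSpec(kind="era"))


class TestEnumerationOracle:
    @pytest.mark.parametrize("kind", ["era", "environmental", "combined"])
    def test_matches_brute_force(self, kind):
        """50 random small instances agree with full latent-state
        enumeration to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            data, params, spec, cov = random_instance(rng, kind)
            ours = marginal_loglik(data, params, spec, cov)
            oracle = brute_force_loglik(data, params, spec, cov)
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestStructuralProperties:
    def test_perfect_detection_reduces_to_bernoulli(self):
        """p = 1 and every interval visited: the marginal likelihood is a
        plain Bernoulli(psi) on 'ever detected per site-era'."""
        rng = np.random.default_rng(3)
        S, J, K, T = 2, 3, 2, 4
        # histories are all-or-nothing (what p = 1 implies)
        d_full = rng.random((S, J, K)) < 0.5
        y = np.repeat(d_full[:, :, :, None], T, axis=3)
        data = make_detection_data(
            S, J, K, T, y, np.ones((J, K, T)), np.ones((S, J))
        )
        alpha = rng.normal(0, 1, S)
        params = OccupancyParams(
            alpha=alpha, psi_era=np.zeros(S), p0=40.0, delta=np.zeros((J, K))
        )
        ll = marginal_loglik(data, params, ModelSpec(kind="era"))
        psi = expit(alpha)
        expected = sum(
            np.log(psi[i]) if d_full[i, j, k] else np.log(1 - psi[i])
            for i in range(S) for j in range(J) for k in range(K)
        )
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_era_and_environmental_share_detection_machinery(self):
        """With all occupancy covariate effects zero, both model kinds give
        identical likelihoods on identical data."""
        rng = np.random.default_rng(4)
        data, params, _, cov = random_instance(rng, "era")
        S = len(params.alpha)
        null = OccupancyParams(
            alpha=params.alpha, p0=params.p0, delta=params.delta,
            psi_era=np.zeros(S), psi_temp=np.zeros(S), psi_temp2=0.0,
            psi_precip=np.zeros(S), psi_floral=np.zeros(S),
        )
        ll_era = marginal_loglik(data, null, ModelSpec(kind="era"), cov)
        ll_env = marginal_loglik(data, null, ModelSpec(kind="environmental"), cov)
        assert ll_era == pytest.approx(ll_env, abs=1e-12)


class TestLinearPredictor:
    def _cov(self, t):
        cov = EraCovariates(
            temp=np.array([[10.0, 20.0]]), precip=np.array([[50.0, 60.0]]),
            floral=np.array([[1.0, 1.2]]),
        ).standardized()
        cov.temp_z = np.full((1, 2), float(t))  # pin the standardized value
        return cov

    def test_all_zero_coefficients_give_half(self):
        params = OccupancyParams(
            alpha=np.zeros(1), psi_temp=np.zeros(1), psi_precip=np.zeros(1),
            psi_floral=np.zeros(1), p0=0.0, delta=np.zeros((1, 2)),
        )
        psi = linear_predictor(
            params, ModelSpec(kind="environmental"), self._cov(0.0), 0, 0, 0
        )
        assert psi == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        params = OccupancyParams(
            alpha=np.zeros(1), psi_temp=np.ones(1), psi_precip=np.zeros(1),
            psi_floral=np.zeros(1), p0=0.0, delta=np.zeros((1, 2)),
        )
        cov = self._cov(-1.0)
        cov.precip_z = np.zeros((1, 2))
        cov.floral_z = np.zeros((1, 2))
        psi = linear_predictor(
            params, ModelSpec(kind="environmental"), cov, 0, 0, 0
        )
        assert psi == pytest.approx(expit(-1.0), abs=1e-5)

    def test_quadratic_vertex(self):
        """With psi_temp2 = -0.3, occupancy peaks at T = -b / (2 * -0.3)."""
        b, c = 0.9, -0.3
        t_star = -b / (2 * c)
        params = OccupancyParams(
            alpha=np.zeros(1), psi_temp=np.array([b]), psi_temp2=c,
            psi_precip=np.zeros(1), psi_floral=np.zeros(1),
            p0=0.0, delta=np.zeros((1, 2)),
        )

        def psi_at(t):
            cov = self._cov(t)
            cov.precip_z = np.zeros((1, 2))
            cov.floral_z = np.zeros((1, 2))
            return linear_predictor(
                params, ModelSpec(kind="environmental"), cov, 0, 0, 0
            )

        peak = psi_at(t_star)
        assert peak > psi_at(t_star - 0.5)
        assert peak > psi_at(t_star + 0.5)

    def test_out_of_range_site_errors(self):
        params = OccupancyParams(
            alpha=np.zeros(1), psi_era=np.zeros(1), p0=0.0, delta=np.zeros((1, 2))
        )
        with pytest.raises(ValueError, match="outside range"):
            linear_predictor(
                params, ModelSpec(kind="era"), None, 0, 0, 0,
                range_mask=np.array([[False]]), n_eras=2,
            )


class TestPosteriorGradient:
    @pytest.mark.parametrize("kind", ["era", "environmental", "combined"])
    def test_analytic_gradient_matches_finite_differences(self, kind):
        rng = np.random.default_rng(11)
        data, _, _, cov = random_instance(rng, kind)
        spec = ModelSpec(
            kind=kind, detection_variant="site_era_ranef_plus_era_fixed",
            include_species_detection_intercept=True,
        )
        stats = SufficientStats.from_data(data, cov)
        layout, logpost = make_log_posterior(spec, stats)
        theta = 0.3 * rng.standard_normal(layout.size)
        _, grad = logpost(theta)
        eps = 1e-6
        for i in range(layout.size):
            e = np.zeros_like(theta)
            e[i] = eps
            num = (logpost(theta + e)[0] - logpost(theta - e)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-4, rel=1e-4)
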