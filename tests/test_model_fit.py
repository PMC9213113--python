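"""Posterior sampling: oracle agreement, reproducibility, and summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from beeshift.covariates import EraCovariates, era_index_z
from beeshift.likelihood import ModelSpec
from beeshift.model import MultiSpeciesOccupancyModel, OccupancyResults
from beeshift.simulate import SimConfig, generate_dataset

from test_likelihood import make_detection_data


def _single_history_data(history):
    """One species, one site, era 1 visited with the given history."""
    T = len(history)
    y = np.zeros((1, 1, 2, T))
    y[0, 0, 0] = history
    visited = np.zeros((1, 2, T), dtype=bool)
    visited[0, 0] = True
    return make_detection_data(1, 1, 2, T, y, visited, [[True]])


def _scale_mixture_density(x, base_var, sd_scales):
    """Density of a centred normal whose variance is base_var plus the
    squares of independent half-normal scale draws, by grid integration."""
    grids = [np.linspace(1e-4, 6 * s, 80) for s in sd_scales]
    dens = np.zeros_like(x, dtype=float)
    if len(grids) == 1:
        w = norm.pdf(grids[0], 0, sd_scales[0])
        w /= w.sum()
        for wi, s in zip(w, grids[0]):
            dens += wi * norm.pdf(x, 0, np.sqrt(base_var + s**2))
    else:
        w0 = norm.pdf(grids[0], 0, sd_scales[0])
        w0 /= w0.sum()
        w1 = norm.pdf(grids[1], 0, sd_scales[1])
        w1 /= w1.sum()
        for wa, sa in zip(w0, grids[0]):
            for wb, sb in zip(w1, grids[1]):
                dens += wa * wb * norm.pdf(
                    x, 0, np.sqrt(base_var + sa**2 + sb**2)
                )
    return dens


class TestQuadratureOracle:
    def test_single_history_posterior_matches_grid_integration(self):
        """On a one-species, one-site-era dataset the sampled posterior of
        psi matches a 2-D grid-quadrature posterior (TV < 0.05).

        The likelihood depends on the parameters only through the two
        logits eta_psi and eta_p, whose priors are scale-mixtures of
        normals computable by 1-D integration; the joint posterior then
        lives on a 2-D grid.
        """
        history = [1, 0, 1, 0]  # d = 2 of V = 4
        data = _single_history_data(history)
        model = MultiSpeciesOccupancyModel(data, kind="era")
        res = model.fit(n_chains=2, n_warmup=500, n_draws=3000, seed=3)
        x0 = era_index_z(2)[0]
        alpha = res.draws_of("alpha")[:, 0]
        slope = res.draws_of("psi_era")[:, 0]
        psi_draws = expit(alpha + slope * x0)

        # oracle: prior(eta_psi) has base variance 2*2.5^2 (two community
        # means) and two half-normal(1.5) scales; prior(eta_p) has base
        # 2.5^2 and one half-normal scale
        eta = np.linspace(-14, 14, 561)
        prior_psi = _scale_mixture_density(eta, 2 * 2.5**2, [1.5, 1.5])
        prior_p = _scale_mixture_density(eta, 2.5**2, [1.5])
        psi_g = expit(eta)[:, None]
        p_g = expit(eta)[None, :]
        d, V = sum(history), len(history)
        lik = psi_g * p_g**d * (1 - p_g) ** (V - d)
        if d == 0:
            lik = lik + (1 - psi_g)
        post = prior_psi[:, None] * prior_p[None, :] * lik
        post_psi = post.sum(axis=1)
        post_psi /= post_psi.sum()

        bins = np.linspace(0, 1, 16)
        oracle_hist = np.zeros(len(bins) - 1)
        which = np.clip(np.digitize(expit(eta), bins) - 1, 0, len(bins) - 2)
        np.add.at(oracle_hist, which, post_psi)
        mcmc_hist, _ = np.histogram(psi_draws, bins=bins)
        mcmc_hist = mcmc_hist / mcmc_hist.sum()
        tv = 0.5 * np.abs(oracle_hist - mcmc_hist).sum()
        assert tv < 0.05


class TestReproducibility:
    def _fit(self, seed):
        cfg = SimConfig(n_species=3, n_sites=8, seed=9)
        data, cov, _ = generate_dataset(cfg, seed=9)
        model = MultiSpeciesOccupancyModel(data, cov, kind="environmental")
        return model.fit(n_chains=2, n_warmup=80, n_draws=80, seed=seed)

    def test_same_seed_bitwise_identical(self):
        r1 = self._fit(5)
        r2 = self._fit(5)
        np.testing.assert_array_equal(r1.run.draws, r2.run.draws)
        assert r1.summary().equals(r2.summary())

    def test_different_seed_differs(self):
        r1 = self._fit(5)
        r2 = self._fit(6)
        assert not np.array_equal(r1.run.draws, r2.run.draws)


def _fake_results(posterior, kind="era", n_eras=6, covariates=None, data=None):
    """Results object with injected draws (no sampling)."""
    if data is None:
        cfg = SimConfig(n_species=posterior[next(iter(posterior))].shape[-1]
                        if posterior[next(iter(posterior))].ndim == 3 else 1,
                        n_sites=4, n_eras=n_eras, seed=0)
        data, cov, _ = generate_dataset(cfg, seed=0)
        covariates = covariates or cov
    model = MultiSpeciesOccupancyModel.__new__(MultiSpeciesOccupancyModel)
    model.spec = ModelSpec(kind=kind)
    model.data = data
    model.covariates = covariates
    return OccupancyResults(model=model, run=None, seed=0, _posterior=posterior)


def _draws3(values_per_species):
    """(1, n_draws, S) array from per-species draw lists."""
    arr = np.array(values_per_species, dtype=float).T  # (draws, S)
    return arr[None, :, :]


class TestSummaries:
    def test_constant_draws_degenerate_bci(self):
        c = 0.37
        res = _fake_results({
            "psi_era": _draws3([[c] * 50]),
            "alpha": _draws3([[0.0] * 50]),
        })
        labels = res.trend_labels()
        assert list(labels)[0] == "increasing"
        s = res.summary()
        assert s.loc[s.index[0], "bci_2.5"] == pytest.approx(c)
        assert s.loc[s.index[0], "bci_97.5"] == pytest.approx(c)

    def test_symmetric_draws_are_stable(self):
        draws = np.concatenate([np.linspace(-1, 1, 101)])
        res = _fake_results({
            "psi_era": _draws3([draws]), "alpha": _draws3([np.zeros(101)]),
        })
        assert list(res.trend_labels())[0] == "stable"

    def test_positive_grid_is_increasing(self):
        draws = np.linspace(0.01, 0.20, 20)
        res = _fake_results({
            "psi_era": _draws3([draws]), "alpha": _draws3([np.zeros(20)]),
        })
        assert list(res.trend_labels())[0] == "increasing"
        # the 2.5th percentile of that grid is above zero by construction
        assert np.percentile(draws, 2.5) > 0


class TestProportionalChange:
    def test_zero_slope_zero_change(self):
        res = _fake_results({
            "psi_era": _draws3([[0.0] * 10]), "alpha": _draws3([[0.7] * 10]),
        })
        np.testing.assert_allclose(res.proportional_change(0), 0.0, atol=1e-14)

    def test_explicit_fractions(self):
        # deterministic draws with psi_first = 0.2, psi_last = 0.3
        x = era_index_z(6)
        slope = (logit(0.3) - logit(0.2)) / (x[-1] - x[0])
        alpha = logit(0.2) - slope * x[0]
        res = _fake_results({
            "psi_era": _draws3([[slope] * 5]), "alpha": _draws3([[alpha] * 5]),
        })
        np.testing.assert_allclose(res.proportional_change(0), 0.5, rtol=1e-10)

    def test_logit_sweep_closed_form(self):
        # logit moves -1 -> +1 across the era span
        x = era_index_z(6)
        slope = 2.0 / (x[-1] - x[0])
        res = _fake_results({
            "psi_era": _draws3([[slope] * 5]), "alpha": _draws3([[0.0] * 5]),
        })
        expected = (expit(1) - expit(-1)) / expit(-1)
        np.testing.assert_allclose(res.proportional_change(0), expected, rtol=1e-9)
        assert expected == pytest.approx(1.7183, abs=1e-4)


class TestThermalOptimum:
    def _env_results(self, mu_temp, temp2, psi_temp=None, n=8):
        cfg = SimConfig(n_species=1, n_sites=4, seed=0)
        data, cov, _ = generate_dataset(cfg, seed=0)
        psi_temp = mu_temp if psi_temp is None else psi_temp
        post = {
            "mu_psi_temp": np.full((1, n), mu_temp),
            "psi_temp2": np.full((1, n), temp2),
            "psi_temp": np.full((1, n, 1), psi_temp),
        }
        return _fake_results(post, kind="environmental", covariates=cov, data=data)

    def test_vertex_formula_on_reported_point_estimates(self):
        # community curvature -0.303 and mean slope -1.574 put the peak at
        # z* = -(-1.574)/(2 * -0.303) = -2.597 standardized units
        res = self._env_results(-1.574, -0.303)
        mean, sd = res.model.covariates.constants["temp"]
        opt = res.thermal_optimum()
        z_star = (opt["community_mean"] - mean) / sd
        assert z_star == pytest.approx(-2.5974, abs=1e-3)

    def test_zero_slope_peaks_at_covariate_mean(self):
        res = self._env_results(0.0, -0.3)
        mean, _ = res.model.covariates.constants["temp"]
        opt = res.thermal_optimum()
        assert opt["community_mean"] == pytest.approx(mean, abs=1e-9)
        assert opt["species_mean"][0] == pytest.approx(mean, abs=1e-9)

    def test_convex_draws_flagged_and_excluded(self):
        cfg = SimConfig(n_species=1, n_sites=4, seed=0)
        data, cov, _ = generate_dataset(cfg, seed=0)
        post = {
            "mu_psi_temp": np.full((1, 4), -1.0),
            "psi_temp2": np.array([[-0.3, -0.3, 0.1, 0.2]]),
            "psi_temp": np.full((1, 4, 1), -1.0),
        }
        res = _fake_results(post, kind="environmental", covariates=cov, data=data)
        assert res.thermal_optimum()["n_flagged_draws"] == 2

    def test_all_convex_errors(self):
        res = self._env_results(-1.0, 0.5)
        with pytest.raises(ValueError, match="concave"):
            res.thermal_optimum()


class TestParameterRecovery:
    def test_community_hyperparameters_within_three_sds(self, recovery_fit):
        """Fit on the full-scale synthetic community recovers every
        community hyperparameter within 3 posterior sds of the truth."""
        results, truth = recovery_fit
        s = results.summary()
        checks = [
            "mu_psi_temp", "psi_temp2", "mu_psi_precip", "mu_psi_floral",
            "sigma_psi_temp", "sigma_psi_precip", "sigma_psi_floral",
            "mu_alpha", "sigma_alpha", "p0", "sigma_p",
        ]
        for name in checks:
            post_mean, post_sd = s.loc[name, "mean"], s.loc[name, "sd"]
            z = (post_mean - truth.hyper[name]) / post_sd
            assert abs(z) < 3.0, f"{name}: z = {z:.2f}"

    def test_diagnostics_converged(self, recovery_fit):
        results, _ = recovery_fit
        assert results.max_rhat() < 1.05
        assert results.run.n_divergent == 0
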