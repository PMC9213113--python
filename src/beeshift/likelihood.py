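"""Marginalized multi-species occupancy likelihood and its gradient.

The observation model, per species i, site j, era k with V visited
5-year intervals and d detections:

    z_ijk ~ Bernoulli(psi_ijk)                    latent occupancy
    y | z=1 ~ independent Bernoulli(p_jk) per visited interval
    y | z=0 = 0

so the marginal likelihood of one detection history is

    L = psi * p^d * (1-p)^(V-d) + (1 - psi) * [d == 0].

The latent z is never sampled: marginalizing it yields a smooth
log-density whose gradient is available in closed form, which is what
lets a gradient-based sampler (NUTS) fit the hierarchical model.
Detection probability is constant across intervals within a site-era
(logit p = p0 + delta_jk, optionally + an era fixed effect and a
species intercept), so (d, V) are sufficient.

Occupancy enters on the logit scale:

    era model:            logit psi = alpha_i + psi_era_i * x_k
    environmental model:  logit psi = alpha_i + psi_temp_i * T_jk
                                      + psi_temp2 * T_jk^2
                                      + psi_precip_i * P_jk
                                      + psi_floral_i * F_jk
    combined:             both sets of terms

with x_k a standardized era index and T, P, F standardized covariates.
Species coefficients are exchangeable draws from community-level normal
distributions (non-centered in the sampler).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

from .covariates import EraCovariates, era_index_z
from .histories import DetectionData

# ---------------------------------------------------------------------------
# Model specification


@dataclass
class PriorConfig:
    """Weakly informative priors on the logit scale.

    Community means, detection intercept, era fixed effect and the
    quadratic temperature term get Normal(0, mean_scale^2); community
    sds and the detection-ranef sd get half-Normal(0, sd_scale^2).
    """

    mean_scale: float = 2.5
    sd_scale: float = 1.5


@dataclass
class ModelSpec:
    """Which occupancy predictors and detection terms the model uses."""

    kind: str = "era"  # era | environmental | combined
    detection_variant: str = "site_era_ranef"  # | site_era_ranef_plus_era_fixed
    include_species_detection_intercept: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.kind not in ("era", "environmental", "combined"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.detection_variant not in (
            "site_era_ranef",
            "site_era_ranef_plus_era_fixed",
        ):
            raise ValueError(f"unknown detection variant {self.detection_variant!r}")

    @property
    def has_era(self) -> bool:
        return self.kind in ("era", "combined")

    @property
    def has_env(self) -> bool:
        return self.kind in ("environmental", "combined")

    @property
    def has_p_era(self) -> bool:
        return self.detection_variant == "site_era_ranef_plus_era_fixed"


@dataclass
class OccupancyParams:
    """One concrete set of model parameters (e.g. one posterior draw).

    Species arrays have length S; ``delta`` is the site x era detection
    random effect (J, K).  Unused families may be left as None.
    """

    alpha: np.ndarray
    p0: float
    delta: np.ndarray
    psi_era: np.ndarray | None = None
    psi_temp: np.ndarray | None = None
    psi_temp2: float = 0.0
    psi_precip: np.ndarray | None = None
    psi_floral: np.ndarray | None = None
    p_era: float = 0.0
    p_species: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Sufficient statistics


@dataclass
class SufficientStats:
    """Detection histories collapsed to per-(species, visited site-era) counts."""

    d: np.ndarray  # (S, n_se) detections
    V: np.ndarray  # (n_se,) visited intervals
    R: np.ndarray  # (S, n_se) in-range mask
    se_site: np.ndarray  # (n_se,) site index of each visited site-era
    se_era: np.ndarray  # (n_se,) era index (0-based)
    x_era: np.ndarray  # (n_se,) standardized era index
    T: np.ndarray | None = None  # (n_se,) standardized temperature
    P: np.ndarray | None = None
    F: np.ndarray | None = None
    n_species: int = 0
    n_sites: int = 0
    n_eras: int = 0

    @classmethod
    def from_data(
        cls, data: DetectionData, covariates: EraCovariates | None = None
    ) -> "SufficientStats":
        V_jk = data.visits_per_site_era()  # (J, K)
        jj, kk = np.nonzero(V_jk)
        d = data.detections_per_site_era()[:, jj, kk]
        stats = cls(
            d=d.astype(float),
            V=V_jk[jj, kk].astype(float),
            R=data.range_mask[:, jj],
            se_site=jj,
            se_era=kk,
            x_era=era_index_z(data.n_eras)[kk],
            n_species=data.n_species,
            n_sites=data.n_sites,
            n_eras=data.n_eras,
        )
        if covariates is not None:
            cov = covariates.require_standardized()
            stats.T = cov.temp_z[jj, kk]
            stats.P = cov.precip_z[jj, kk]
            stats.F = cov.floral_z[jj, kk]
        return stats

    @property
    def n_se(self) -> int:
        return self.V.shape[0]


# ---------------------------------------------------------------------------
# Core marginal likelihood (shared by the public op and the sampler)


def _history_loglik_terms(eta_psi, eta_p, d, V, R):
    """Per-(species, site-era) marginal log-likelihood and gradients.

    Returns (ll_total, G_psi, G_p) where G_psi = dll/d eta_psi and
    G_p = dll/d eta_p, both (S, n_se) and already masked by R.

    Writing W for the posterior probability that the species occupies
    the site-era given its history, the gradients take the compact form
    G_psi = W - psi and G_p = W * (d - V p).
    """
    psi = expit(eta_psi)
    p = expit(eta_p)
    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)
    logq = d * log_expit(eta_p) + (V - d) * log_expit(-eta_p)
    occ_branch = log_psi + logq
    # d == 0 histories also admit the unoccupied branch
    all_zero = d == 0
    ll = np.where(all_zero, np.logaddexp(occ_branch, log_1mpsi), occ_branch)
    W = np.exp(occ_branch - ll)  # == 1 exactly when d > 0
    G_psi = (W - psi) * R
    G_p = W * (d - V * p) * R
    return float((ll * R).sum()), G_psi, G_p


def species_linear_predictor(
    params: OccupancyParams, spec: ModelSpec, stats: SufficientStats
) -> np.ndarray:
    """logit psi as an (S, n_se) array."""
    eta = np.repeat(params.alpha[:, None], stats.n_se, axis=1)
    if spec.has_era:
        eta = eta + params.psi_era[:, None] * stats.x_era[None, :]
    if spec.has_env:
        eta = eta + (
            params.psi_temp[:, None] * stats.T[None, :]
            + params.psi_temp2 * (stats.T**2)[None, :]
            + params.psi_precip[:, None] * stats.P[None, :]
            + params.psi_floral[:, None] * stats.F[None, :]
        )
    return eta


def detection_logit(
    params: OccupancyParams, spec: ModelSpec, stats: SufficientStats
) -> np.ndarray:
    """logit p as (n_se,) or (S, n_se) if species intercepts are on."""
    eta = params.p0 + params.delta[stats.se_site, stats.se_era]
    if spec.has_p_era:
        eta = eta + params.p_era * stats.x_era
    if spec.include_species_detection_intercept:
        eta = eta[None, :] + params.p_species[:, None]
    return eta


def marginal_loglik(
    data: DetectionData,
    params: OccupancyParams,
    spec: ModelSpec,
    covariates: EraCovariates | None = None,
) -> float:
    """Total marginal log-likelihood of the detection data.

    Latent occupancy states are summed out analytically; unvisited
    intervals and out-of-range sites contribute nothing.
    """
    if np.any(data.y & ~data.visited[None, :, :, :]):
        raise AssertionError("detection recorded at an unvisited interval")
    stats = SufficientStats.from_data(data, covariates)
    eta_psi = species_linear_predictor(params, spec, stats)
    eta_p = detection_logit(params, spec, stats)
    if eta_p.ndim == 1:
        eta_p = eta_p[None, :]
    ll, _, _ = _history_loglik_terms(eta_psi, eta_p, stats.d, stats.V, stats.R)
    return ll


def linear_predictor(
    params: OccupancyParams,
    spec: ModelSpec,
    covariates: EraCovariates | None,
    species: int,
    site: int,
    era: int,
    *,
    range_mask: np.ndarray | None = None,
    n_eras: int | None = None,
) -> float:
    """Occupancy probability psi for one species x site x era."""
    if range_mask is not None and not range_mask[species, site]:
        raise ValueError(f"site {site} outside range of species {species}")
    eta = params.alpha[species]
    if spec.has_era:
        if n_eras is None:
            n_eras = covariates.n_eras if covariates is not None else 6
        eta += params.psi_era[species] * era_index_z(n_eras)[era]
    if spec.has_env:
        cov = covariates.require_standardized()
        t = cov.temp_z[site, era]
        eta += (
            params.psi_temp[species] * t
            + params.psi_temp2 * t**2
            + params.psi_precip[species] * cov.precip_z[site, era]
            + params.psi_floral[species] * cov.floral_z[site, era]
        )
    return float(expit(eta))


# ---------------------------------------------------------------------------
# Flat-vector posterior for the sampler

#: hierarchical coefficient families by model kind
FAMILIES = {
    "era": ("alpha", "psi_era"),
    "environmental": ("alpha", "psi_temp", "psi_precip", "psi_floral"),
    "combined": ("alpha", "psi_era", "psi_temp", "psi_precip", "psi_floral"),
}


class ParameterLayout:
    """Maps named blocks onto a flat unconstrained vector.

    Each hierarchical family occupies (mu, log_sigma, raw[S]) with the
    non-centered transform value = mu + exp(log_sigma) * raw.  The
    detection block holds p0, log_sigma_p and one raw random effect per
    *visited* site-era (unvisited site-eras carry no information about
    delta and are dropped from the vector).
    """

    def __init__(self, spec: ModelSpec, stats: SufficientStats):
        self.spec = spec
        self.stats = stats
        S, n_se = stats.n_species, stats.n_se
        self.blocks: dict[str, slice] = {}
        pos = 0

        def add(name: str, size: int):
            nonlocal pos
            self.blocks[name] = slice(pos, pos + size)
            pos += size

        for fam in FAMILIES[spec.kind]:
            add(f"mu_{fam}", 1)
            add(f"log_sigma_{fam}", 1)
            add(f"{fam}_raw", S)
        if spec.has_env:
            add("psi_temp2", 1)
        add("p0", 1)
        add("log_sigma_p", 1)
        add("delta_raw", n_se)
        if spec.has_p_era:
            add("p_era", 1)
        if spec.include_species_detection_intercept:
            add("log_sigma_p_species", 1)
            add("p_species_raw", S)
        self.size = pos

    def get(self, theta: np.ndarray, name: str):
        v = theta[self.blocks[name]]
        # family raws stay vectors even for a single species
        if name.endswith("_raw"):
            return v
        return v[0] if v.shape == (1,) else v

    def unpack(self, theta: np.ndarray) -> dict:
        """Flat vector -> named natural-scale parameter dict."""
        out = {}
        for fam in FAMILIES[self.spec.kind]:
            mu = self.get(theta, f"mu_{fam}")
            sigma = np.exp(self.get(theta, f"log_sigma_{fam}"))
            out[f"mu_{fam}"] = mu
            out[f"sigma_{fam}"] = sigma
            out[fam] = mu + sigma * self.get(theta, f"{fam}_raw")
        if self.spec.has_env:
            out["psi_temp2"] = self.get(theta, "psi_temp2")
        out["p0"] = self.get(theta, "p0")
        out["sigma_p"] = np.exp(self.get(theta, "log_sigma_p"))
        out["delta_se"] = out["sigma_p"] * self.get(theta, "delta_raw")
        if self.spec.has_p_era:
            out["p_era"] = self.get(theta, "p_era")
        if self.spec.include_species_detection_intercept:
            out["sigma_p_species"] = np.exp(self.get(theta, "log_sigma_p_species"))
            out["p_species"] = out["sigma_p_species"] * self.get(
                theta, "p_species_raw"
            )
        return out

    def to_params(self, theta: np.ndarray) -> OccupancyParams:
        """Flat vector -> :class:`OccupancyParams` (delta scattered to (J, K))."""
        u = self.unpack(theta)
        delta = np.zeros((self.stats.n_sites, self.stats.n_eras))
        delta[self.stats.se_site, self.stats.se_era] = u["delta_se"]
        return OccupancyParams(
            alpha=u["alpha"],
            p0=u["p0"],
            delta=delta,
            psi_era=u.get("psi_era"),
            psi_temp=u.get("psi_temp"),
            psi_temp2=u.get("psi_temp2", 0.0),
            psi_precip=u.get("psi_precip"),
            psi_floral=u.get("psi_floral"),
            p_era=u.get("p_era", 0.0),
            p_species=u.get("p_species"),
        )


def make_log_posterior(spec: ModelSpec, stats: SufficientStats):
    """Build ``f(theta) -> (log posterior, gradient)`` for the sampler.

    The density is the marginal log-likelihood plus hierarchical priors,
    on the unconstrained non-centered parameterization (log-transformed
    sds include the Jacobian term).
    """
    layout = ParameterLayout(spec, stats)
    pri = spec.priors
    mean_var = pri.mean_scale**2
    sd_var = pri.sd_scale**2
    S = stats.n_species
    fams = FAMILIES[spec.kind]
    d, V, R = stats.d, stats.V, stats.R
    x_era, T, P, F = stats.x_era, stats.T, stats.P, stats.F
    T2 = T**2 if T is not None else None

    def logpost(theta: np.ndarray):
        grad = np.zeros_like(theta)
        u = layout.unpack(theta)

        # linear predictors
        eta_psi = np.repeat(u["alpha"][:, None], stats.n_se, axis=1)
        if spec.has_era:
            eta_psi += u["psi_era"][:, None] * x_era[None, :]
        if spec.has_env:
            eta_psi += (
                u["psi_temp"][:, None] * T[None, :]
                + u["psi_temp2"] * T2[None, :]
                + u["psi_precip"][:, None] * P[None, :]
                + u["psi_floral"][:, None] * F[None, :]
            )
        eta_p_se = u["p0"] + u["delta_se"]
        if spec.has_p_era:
            eta_p_se = eta_p_se + u["p_era"] * x_era
        if spec.include_species_detection_intercept:
            eta_p = eta_p_se[None, :] + u["p_species"][:, None]
        else:
            eta_p = eta_p_se[None, :]

        lp, G_psi, G_p = _history_loglik_terms(eta_psi, eta_p, d, V, R)
        G_p_se = G_p.sum(axis=0)

        # occupancy families (non-centered): value_i = mu + sigma * raw_i
        fam_grads = {"alpha": G_psi.sum(axis=1)}
        if spec.has_era:
            fam_grads["psi_era"] = G_psi @ x_era
        if spec.has_env:
            fam_grads["psi_temp"] = G_psi @ T
            fam_grads["psi_precip"] = G_psi @ P
            fam_grads["psi_floral"] = G_psi @ F
        for fam in fams:
            g = fam_grads[fam]
            mu = u[f"mu_{fam}"]
            sigma = u[f"sigma_{fam}"]
            raw = layout.get(theta, f"{fam}_raw")
            lp += -0.5 * mu**2 / mean_var  # prior on community mean
            lp += -0.5 * sigma**2 / sd_var + np.log(sigma)  # half-N + Jacobian
            lp += -0.5 * float(raw @ raw)  # standard-normal raws
            grad[layout.blocks[f"mu_{fam}"]] = g.sum() - mu / mean_var
            grad[layout.blocks[f"log_sigma_{fam}"]] = (
                sigma * float(raw @ g) - sigma**2 / sd_var + 1.0
            )
            grad[layout.blocks[f"{fam}_raw"]] = sigma * g - raw

        if spec.has_env:
            t2 = u["psi_temp2"]
            lp += -0.5 * t2**2 / mean_var
            grad[layout.blocks["psi_temp2"]] = float(
                (G_psi * T2[None, :]).sum()
            ) - t2 / mean_var

        # detection block
        p0 = u["p0"]
        sigma_p = u["sigma_p"]
        delta_raw = layout.get(theta, "delta_raw")
        lp += -0.5 * p0**2 / mean_var
        lp += -0.5 * sigma_p**2 / sd_var + np.log(sigma_p)
        lp += -0.5 * float(delta_raw @ delta_raw)
        grad[layout.blocks["p0"]] = G_p_se.sum() - p0 / mean_var
        grad[layout.blocks["log_sigma_p"]] = (
            sigma_p * float(delta_raw @ G_p_se) - sigma_p**2 / sd_var + 1.0
        )
        grad[layout.blocks["delta_raw"]] = sigma_p * G_p_se - delta_raw
        if spec.has_p_era:
            pe = u["p_era"]
            lp += -0.5 * pe**2 / mean_var
            grad[layout.blocks["p_era"]] = float(G_p_se @ x_era) - pe / mean_var
        if spec.include_species_detection_intercept:
            g_sp = G_p.sum(axis=1)
            sig = u["sigma_p_species"]
            raw = layout.get(theta, "p_species_raw")
            lp += -0.5 * sig**2 / sd_var + np.log(sig)
            lp += -0.5 * float(raw @ raw)
            grad[layout.blocks["log_sigma_p_species"]] = (
                sig * float(raw @ g_sp) - sig**2 / sd_var + 1.0
            )
            grad[layout.blocks["p_species_raw"]] = sig * g_sp - raw

        return lp, grad

    return layout, logpost
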