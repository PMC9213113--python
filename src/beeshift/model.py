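"""Model and results objects for the multi-species occupancy analysis.

Follows the fit-then-inspect idiom of statistical modelling packages:

>>> model = MultiSpeciesOccupancyModel(data, covariates, kind="environmental")
>>> res = model.fit(seed=1)
>>> res.summary()                      # community hyperparameters
>>> res.species_table()                # per-species coefficients + labels
>>> res.thermal_optimum()              # community optimum in degC

Two model kinds answer two questions: the *era* model asks whether
occupancy trends through time (a logit-linear trend on a standardized
era index, species slopes psi_era[i] drawn around a community mean
mu_psi_era); the *environmental* model replaces time with standardized
temperature (linear per species + one community quadratic),
precipitation and floral-resource predictors.  "combined" includes
both.  Both share identical detection machinery: a site- and
era-specific random effect on logit detection probability, optionally
plus a fixed era effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import EraCovariates, era_index_z
from .histories import DetectionData
from .likelihood import (
    FAMILIES,
    ModelSpec,
    OccupancyParams,
    PriorConfig,
    SufficientStats,
    make_log_posterior,
    marginal_loglik,
)
from .mcmc import NUTSConfig, SamplerRun, sample_nuts

logger = logging.getLogger(__name__)

__all__ = [
    "MultiSpeciesOccupancyModel",
    "OccupancyResults",
    "ModelSpec",
    "PriorConfig",
    "OccupancyParams",
]


class MultiSpeciesOccupancyModel:
    """Hierarchical multi-species occupancy model on detection histories.

    Parameters
    ----------
    data
        Detection/non-detection array with visit and range masks.
    covariates
        Site x era environmental predictors; required for
        ``kind="environmental"`` or ``"combined"``.  Standardized on
        construction if not already.
    kind, detection_variant, priors, spec
        Model structure; pass either a full :class:`ModelSpec` or the
        individual fields.
    """

    def __init__(
        self,
        data: DetectionData,
        covariates: EraCovariates | None = None,
        *,
        kind: str = "era",
        detection_variant: str = "site_era_ranef",
        include_species_detection_intercept: bool = False,
        priors: PriorConfig | None = None,
        spec: ModelSpec | None = None,
    ):
        self.spec = spec or ModelSpec(
            kind=kind,
            detection_variant=detection_variant,
            include_species_detection_intercept=include_species_detection_intercept,
            priors=priors or PriorConfig(),
        )
        if self.spec.has_env and covariates is None:
            raise ValueError(f"{self.spec.kind!r} model requires covariates")
        if covariates is not None:
            if covariates.n_sites != data.n_sites or covariates.n_eras != data.n_eras:
                raise ValueError(
                    "covariates shape "
                    f"({covariates.n_sites}, {covariates.n_eras}) does not match "
                    f"data ({data.n_sites}, {data.n_eras})"
                )
            covariates = covariates.require_standardized()
        data.validate()
        self.data = data
        self.covariates = covariates
        self.stats = SufficientStats.from_data(data, covariates)
        self.layout, self.logpost = make_log_posterior(self.spec, self.stats)

    def loglik(self, params: OccupancyParams) -> float:
        """Marginal log-likelihood of the data at given parameters."""
        return marginal_loglik(self.data, params, self.spec, self.covariates)

    def fit(
        self,
        *,
        n_chains: int = 4,
        n_warmup: int = 1000,
        n_draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.8,
        max_treedepth: int = 10,
    ) -> "OccupancyResults":
        """Sample the posterior with NUTS on the marginalized likelihood.

        Deterministic given ``seed``.  Warns if any split R-hat among
        the community-level and species-level parameters exceeds 1.05.
        """
        cfg = NUTSConfig(
            n_warmup=n_warmup,
            n_draws=n_draws,
            n_chains=n_chains,
            max_treedepth=max_treedepth,
            target_accept=target_accept,
        )
        init = np.zeros(self.layout.size)
        run = sample_nuts(self.logpost, init, cfg, seed)
        res = OccupancyResults(model=self, run=run, seed=seed)
        bad = res.max_rhat()
        if bad > 1.05:
            warnings.warn(
                f"split R-hat up to {bad:.3f} > 1.05; consider longer chains",
                stacklevel=2,
            )
        if run.n_divergent:
            logger.info("sampler reported %d divergent transitions", run.n_divergent)
        return res


@dataclass
class OccupancyResults:
    """Posterior draws, diagnostics and derived quantities of one fit."""

    model: MultiSpeciesOccupancyModel
    run: SamplerRun
    seed: int
    _posterior: dict = field(default=None, repr=False)

    # -- draw bookkeeping ---------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def posterior(self) -> dict:
        """Named draws: scalars (chain, draw), species arrays (chain, draw, S)."""
        if self._posterior is None:
            layout = self.model.layout
            flat = self.run.draws  # (chains, draws, dim)
            C, D, _ = flat.shape
            unpacked = [
                [layout.unpack(flat[c, d]) for d in range(D)] for c in range(C)
            ]
            names = [
                k
                for k in unpacked[0][0]
                if k != "delta_se"
            ]
            post = {}
            for name in names:
                post[name] = np.array(
                    [[unpacked[c][d][name] for d in range(D)] for c in range(C)]
                )
            post["delta_se"] = np.array(
                [[unpacked[c][d]["delta_se"] for d in range(D)] for c in range(C)]
            )
            self._posterior = post
        return self._posterior

    def draws_of(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter, chains stacked first."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        """Package draws as an :class:`arviz.InferenceData`."""
        import arviz as az

        post = {
            k: v
            for k, v in self.posterior.items()
            if k != "delta_se"
        }
        coords = {"species": self.model.data.species}
        dims = {
            k: ["species"] for k, v in post.items() if v.ndim == 3
        }
        return az.from_dict(
            posterior=post,
            coords=coords,
            dims=dims,
            sample_stats={
                "acceptance_rate": self.run.accept_prob,
                "tree_depth": self.run.tree_depth,
            },
        )

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and bulk/tail ESS per parameter (arviz)."""
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.summary(self.to_inference_data(), kind="diagnostics")

    def max_rhat(self) -> float:
        import arviz as az

        idata = self.to_inference_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
        return float(
            max(np.nanmax(np.atleast_1d(v.values)) for v in rhat.data_vars.values())
        )

    # -- summaries ----------------------------------------------------------

    @staticmethod
    def _bci(draws: np.ndarray, axis: int = 0) -> tuple:
        lo = np.percentile(draws, 2.5, axis=axis)
        hi = np.percentile(draws, 97.5, axis=axis)
        return lo, hi

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and equal-tailed 95% BCI per parameter.

        Community-level rows plus one row per species coefficient.
        """
        rows = []
        for name, arr in self.posterior.items():
            if name == "delta_se":
                continue
            pooled = arr.reshape(-1, *arr.shape[2:])
            if pooled.ndim == 1:
                lo, hi = self._bci(pooled)
                rows.append((name, pooled.mean(), pooled.std(), lo, hi))
            else:
                lo, hi = self._bci(pooled, axis=0)
                for i, sp in enumerate(self.model.data.species):
                    rows.append(
                        (f"{name}[{sp}]", pooled[:, i].mean(), pooled[:, i].std(),
                         lo[i], hi[i])
                    )
        return pd.DataFrame(
            rows, columns=["parameter", "mean", "sd", "bci_2.5", "bci_97.5"]
        ).set_index("parameter")

    def trend_labels(self, family: str = "psi_era") -> pd.Series:
        """increasing / decreasing / stable per species.

        A species is *increasing* if the 95% BCI of its coefficient lies
        entirely above zero, *decreasing* if entirely below, otherwise
        *stable*.
        """
        draws = self.draws_of(family)
        lo, hi = self._bci(draws, axis=0)
        labels = np.where(lo > 0, "increasing", np.where(hi < 0, "decreasing", "stable"))
        return pd.Series(labels, index=self.model.data.species, name=f"trend_{family}")

    def proportional_change(self, species: int | None = None) -> np.ndarray:
        """Posterior of (psi_last - psi_first) / psi_first per species.

        Era-model quantity: occupancy at the species' own intercept and
        era slope, eras at their standardized index values.  Returns
        (n_draws,) for one species or (n_draws, S) for all.
        """
        if not self.spec.has_era:
            raise ValueError("proportional change requires an era-model fit")
        x = era_index_z(self.model.data.n_eras)
        alpha = self.draws_of("alpha")
        slope = self.draws_of("psi_era")
        if species is not None:
            alpha, slope = alpha[:, species], slope[:, species]
        psi_first = expit(alpha + slope * x[0])
        psi_last = expit(alpha + slope * x[-1])
        return (psi_last - psi_first) / psi_first

    def thermal_optimum(self) -> dict:
        """Temperature of peak occupancy, in degC.

        Per draw the logit-quadratic in standardized temperature peaks at
        z* = -psi_temp / (2 psi_temp2); draws with a non-concave profile
        (psi_temp2 >= 0) are excluded and counted.  z* is mapped back to
        degC with the saved standardization constants.
        """
        if not self.spec.has_env:
            raise ValueError("thermal optimum requires an environmental-model fit")
        temp2 = self.draws_of("psi_temp2")
        valid = temp2 < 0
        n_flagged = int((~valid).sum())
        if not valid.any():
            raise ValueError("no draws with concave temperature response")
        if n_flagged:
            logger.info(
                "thermal_optimum: excluded %d draws with psi_temp2 >= 0", n_flagged
            )
        mean, sd = self.model.covariates.constants["temp"]
        z_comm = -self.draws_of("mu_psi_temp")[valid] / (2.0 * temp2[valid])
        z_sp = -self.draws_of("psi_temp")[valid] / (2.0 * temp2[valid, None])
        comm = mean + sd * z_comm
        sp = mean + sd * z_sp
        lo, hi = self._bci(comm)
        sp_lo, sp_hi = self._bci(sp, axis=0)
        return {
            "community_mean": float(comm.mean()),
            "community_bci": (float(lo), float(hi)),
            "community_draws": comm,
            "species_mean": sp.mean(axis=0),
            "species_bci": np.stack([sp_lo, sp_hi]),
            "n_flagged_draws": n_flagged,
        }

    def species_table(self) -> pd.DataFrame:
        """Per-species coefficient table with BCIs and trend labels."""
        rows = {"species": self.model.data.species}
        fams = [f for f in FAMILIES[self.spec.kind] if f != "alpha"]
        for fam in fams:
            draws = self.draws_of(fam)
            lo, hi = self._bci(draws, axis=0)
            rows[fam] = draws.mean(axis=0)
            rows[f"{fam}_lo"] = lo
            rows[f"{fam}_hi"] = hi
        df = pd.DataFrame(rows).set_index("species")
        if self.spec.has_era:
            df["trend"] = self.trend_labels().to_numpy()
            pc = self.proportional_change()
            lo, hi = self._bci(pc, axis=0)
            df["prop_change"] = pc.mean(axis=0)
            df["prop_change_lo"] = lo
            df["prop_change_hi"] = hi
        return df

    def params_at(self, chain: int, draw: int) -> OccupancyParams:
        """One posterior draw as :class:`OccupancyParams`."""
        return self.model.layout.to_params(self.run.draws[chain, draw])

    def mean_params(self) -> OccupancyParams:
        """Parameters at the posterior mean of the flat vector."""
        flat = self.run.draws.reshape(-1, self.run.draws.shape[-1]).mean(axis=0)
        return self.model.layout.to_params(flat)
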