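"""Counterfactual decomposition: climate-change winners and losers.

For each species the environmental model implies a change in occupancy
between the first and last era that is *entirely* a function of how
temperature, precipitation and floral resources changed at the sites in
its range.  Holding one covariate fixed at its (per-site, across-era)
mean removes that covariate's temporal change while preserving spatial
gradients; comparing the actual change (delta_actual) against the
held-constant change (delta_held) attributes the difference to the held
covariate.  Species whose change flips sign entirely — credibly
positive under stasis, credibly negative under the observed covariate
trajectory — are "winners turned losers" (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import EraCovariates
from .model import OccupancyResults

__all__ = [
    "CounterfactualResult",
    "occupancy_change",
    "classify",
    "winners_losers_table",
]

HOLDABLE = ("temp", "precip", "floral")


@dataclass
class CounterfactualResult:
    """Per-species posterior of delta-occupancy, actual vs held-constant."""

    species: str
    variable_held: str | None
    delta_actual: np.ndarray  # posterior draws
    delta_held: np.ndarray
    label: str


def _held_matrix(z: np.ndarray, hold_mode: str) -> np.ndarray:
    """Covariate matrix with temporal change removed.

    ``site_mean``: each site pinned at its own across-era mean
    (preserves spatial gradients); ``global_mean``: everything at the
    overall mean.
    """
    if hold_mode == "site_mean":
        return np.repeat(z.mean(axis=1, keepdims=True), z.shape[1], axis=1)
    if hold_mode == "global_mean":
        return np.full_like(z, z.mean())
    raise ValueError(f"unknown hold_mode {hold_mode!r}")


def occupancy_change(
    results: OccupancyResults,
    species: int,
    *,
    hold: str | None = None,
    hold_mode: str = "site_mean",
    first_era: int = 0,
    last_era: int = -1,
) -> np.ndarray:
    """Posterior draws of the first-to-last-era occupancy change.

    Per draw, Delta = mean over the species' in-range sites of
    psi(last era) - psi(first era), evaluated on standardized
    covariates.  With ``hold`` in {"temp", "precip", "floral"} that
    covariate is replaced (in both eras) by its held-constant version
    before evaluating psi; the quadratic temperature term is part of the
    fitted surface and is always included.
    """
    if not results.spec.has_env:
        raise ValueError("occupancy_change requires an environmental-model fit")
    if hold is not None and hold not in HOLDABLE:
        raise ValueError(f"hold must be one of {HOLDABLE} or None")
    cov: EraCovariates = results.model.covariates
    in_range = np.flatnonzero(results.model.data.range_mask[species])
    if in_range.size < 1:
        raise ValueError(f"species {species} has no in-range sites")

    Z = {"temp": cov.temp_z, "precip": cov.precip_z, "floral": cov.floral_z}
    if hold is not None:
        Z = dict(Z)
        Z[hold] = _held_matrix(Z[hold], hold_mode)

    alpha = results.draws_of("alpha")[:, species]  # (n_draws,)
    b_t = results.draws_of("psi_temp")[:, species]
    b_t2 = results.draws_of("psi_temp2")
    b_p = results.draws_of("psi_precip")[:, species]
    b_f = results.draws_of("psi_floral")[:, species]

    def psi(era_col: int) -> np.ndarray:  # (n_draws, n_in_range_sites)
        T = Z["temp"][in_range, era_col][None, :]
        P = Z["precip"][in_range, era_col][None, :]
        F = Z["floral"][in_range, era_col][None, :]
        eta = (
            alpha[:, None]
            + b_t[:, None] * T
            + b_t2[:, None] * T**2
            + b_p[:, None] * P
            + b_f[:, None] * F
        )
        return expit(eta)

    eras = range(results.model.data.n_eras)
    first = eras[first_era]
    last = eras[last_era]
    return (psi(last) - psi(first)).mean(axis=1)


def classify(delta_actual: np.ndarray, delta_held: np.ndarray) -> str:
    """Label the paired actual-vs-held posterior.

    The paired difference D = delta_actual - delta_held is the vertical
    distance to the 1:1 line, per draw.  If its 95% BCI covers zero the
    species is ``unaffected``.  Otherwise, a full sign flip — held BCI
    entirely positive with actual BCI entirely negative — is
    ``winner_to_loser`` (mirrored: ``loser_to_winner``); remaining cases
    are ``affected_negative``/``affected_positive`` by the sign of
    mean(D).
    """
    delta_actual = np.asarray(delta_actual, dtype=float)
    delta_held = np.asarray(delta_held, dtype=float)
    if delta_actual.shape != delta_held.shape:
        raise ValueError("delta_actual and delta_held must have equal draw counts")
    diff = delta_actual - delta_held
    d_lo, d_hi = np.percentile(diff, [2.5, 97.5])
    if d_lo <= 0.0 <= d_hi:
        return "unaffected"
    h_lo, h_hi = np.percentile(delta_held, [2.5, 97.5])
    a_lo, a_hi = np.percentile(delta_actual, [2.5, 97.5])
    if h_lo > 0 and a_hi < 0:
        return "winner_to_loser"
    if h_hi < 0 and a_lo > 0:
        return "loser_to_winner"
    return "affected_negative" if diff.mean() < 0 else "affected_positive"


def counterfactual_for(
    results: OccupancyResults,
    species: int,
    variable_held: str | None,
    *,
    hold_mode: str = "site_mean",
) -> CounterfactualResult:
    actual = occupancy_change(results, species, hold=None)
    if variable_held is None:
        return CounterfactualResult(
            species=results.model.data.species[species],
            variable_held=None,
            delta_actual=actual,
            delta_held=actual,
            label="unaffected",
        )
    held = occupancy_change(results, species, hold=variable_held, hold_mode=hold_mode)
    return CounterfactualResult(
        species=results.model.data.species[species],
        variable_held=variable_held,
        delta_actual=actual,
        delta_held=held,
        label=classify(actual, held),
    )


def winners_losers_table(
    results: OccupancyResults,
    *,
    variables: tuple = HOLDABLE,
    hold_mode: str = "site_mean",
) -> pd.DataFrame:
    """Per-species, per-variable counterfactual table.

    One row per (species, variable_held) with posterior mean and 95% BCI
    of delta_actual, delta_held and their paired difference D, plus the
    label.  A species counts as *negatively impacted* by a variable when
    mean(D) < 0: its occupancy change under the observed covariate
    trajectory is worse than it would have been under stasis.
    """
    rows = []
    n_species = results.model.data.n_species
    for v in variables:
        for i in range(n_species):
            cf = counterfactual_for(results, i, v, hold_mode=hold_mode)
            diff = cf.delta_actual - cf.delta_held
            rec = {"species": cf.species, "variable_held": v, "label": cf.label}
            for name, draws in (
                ("delta_actual", cf.delta_actual),
                ("delta_held", cf.delta_held),
                ("D", diff),
            ):
                lo, hi = np.percentile(draws, [2.5, 97.5])
                rec[f"{name}_mean"] = float(draws.mean())
                rec[f"{name}_lo"] = float(lo)
                rec[f"{name}_hi"] = float(hi)
            rec["negatively_impacted"] = rec["D_mean"] < 0
            rows.append(rec)
    return pd.DataFrame(rows)


def impact_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of negatively/positively impacted species per variable."""
    neg = table.groupby("variable_held")["negatively_impacted"].sum().astype(int)
    pos = (
        table.assign(pos=table["D_mean"] > 0)
        .groupby("variable_held")["pos"]
        .sum()
        .astype(int)
    )
    return pd.DataFrame({"n_negative": neg, "n_positive": pos})


def fig2_scatter_spec(table: pd.DataFrame) -> dict:
    """Plot specification for the three-panel actual-vs-held scatter."""
    panels = {}
    for v, sub in table.groupby("variable_held"):
        panels[v] = {
            "x": "delta_held",
            "y": "delta_actual",
            "xerr": ["delta_held_lo", "delta_held_hi"],
            "yerr": ["delta_actual_lo", "delta_actual_hi"],
            "reference_line": "1:1",
            "points": sub.drop(columns=["variable_held"]).to_dict("records"),
        }
    return {"kind": "winners_losers_scatter", "panels": panels}
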