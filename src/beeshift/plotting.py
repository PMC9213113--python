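"""Figures for fitted occupancy models and counterfactual tables."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .covariates import era_index_z


def plot_era_trends(results, ax=None):
    """Species occupancy trajectories over eras plus the community mean.

    Grey curves: per-species posterior-mean occupancy vs era; black
    curve with band: community trajectory (posterior mean of mu_alpha /
    mu_psi_era) and its 95% BCI.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    K = results.model.data.n_eras
    x = era_index_z(K)
    eras = np.arange(1, K + 1)
    alpha = results.draws_of("alpha")
    slope = results.draws_of("psi_era")
    for i in range(alpha.shape[1]):
        psi = expit(alpha[:, i].mean() + slope[:, i].mean() * x)
        ax.plot(eras, psi, color="grey", alpha=0.5, lw=1)
    mu_a = results.draws_of("mu_alpha")
    mu_s = results.draws_of("mu_psi_era")
    comm = expit(mu_a[:, None] + mu_s[:, None] * x[None, :])
    ax.plot(eras, comm.mean(axis=0), color="red", lw=2)
    lo, hi = np.percentile(comm, [2.5, 97.5], axis=0)
    ax.fill_between(eras, lo, hi, color="red", alpha=0.2)
    ax.set_xlabel("era")
    ax.set_ylabel("occupancy probability")
    return ax


def plot_winners_losers(table, axes=None):
    """Three-panel actual vs held-constant occupancy-change scatter.

    One panel per held variable; the 1:1 line marks "no effect of this
    covariate's temporal change"; point colour encodes the label
    (grey = unaffected, black = shifted, red = winner-to-loser,
    blue = loser-to-winner).
    """
    import matplotlib.pyplot as plt

    variables = table["variable_held"].unique()
    if axes is None:
        _, axes = plt.subplots(1, len(variables), figsize=(4 * len(variables), 4))
        axes = np.atleast_1d(axes)
    colors = {
        "unaffected": "lightgrey",
        "affected_negative": "black",
        "affected_positive": "black",
        "winner_to_loser": "red",
        "loser_to_winner": "blue",
    }
    for ax, v in zip(axes, variables):
        sub = table[table["variable_held"] == v]
        for _, row in sub.iterrows():
            c = colors[row["label"]]
            ax.plot(
                [row["delta_held_lo"], row["delta_held_hi"]],
                [row["delta_actual_mean"]] * 2, color=c, alpha=0.5, lw=1,
            )
            ax.plot(
                [row["delta_held_mean"]] * 2,
                [row["delta_actual_lo"], row["delta_actual_hi"]],
                color=c, alpha=0.5, lw=1,
            )
            ax.scatter(row["delta_held_mean"], row["delta_actual_mean"],
                       color=c, zorder=3, s=18)
        lims = ax.get_xlim() + ax.get_ylim()
        lo, hi = min(lims), max(lims)
        ax.plot([lo, hi], [lo, hi], ls="--", color="grey", lw=1)
        ax.set_title(f"held: {v}")
        ax.set_xlabel("delta occupancy, covariate held")
        ax.set_ylabel("delta occupancy, actual")
    return axes
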