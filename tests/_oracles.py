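"""Independent oracles for likelihood verification.

The enumeration oracle works directly from the 4-D y/visited/range
arrays and explicitly sums over every configuration of the latent
occupancy vector z in {0,1}^(species x site-era) — deliberately naive
and independent of the package's sufficient-statistic factorization.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit


def era_index(n_eras: int) -> np.ndarray:
    idx = np.arange(1, n_eras + 1, dtype=float)
    return (idx - idx.mean()) / idx.std()


def brute_force_loglik(data, params, spec, covariates=None) -> float:
    """Log-likelihood by exhaustive latent-state enumeration."""
    S, J, K, T = data.y.shape
    x = era_index(K)

    def psi_of(i, j, k):
        eta = params.alpha[i]
        if spec.has_era:
            eta += params.psi_era[i] * x[k]
        if spec.has_env:
            t = covariates.temp_z[j, k]
            eta += (
                params.psi_temp[i] * t
                + params.psi_temp2 * t**2
                + params.psi_precip[i] * covariates.precip_z[j, k]
                + params.psi_floral[i] * covariates.floral_z[j, k]
            )
        return expit(eta)

    def p_of(j, k):
        eta = params.p0 + params.delta[j, k]
        if spec.has_p_era:
            eta += params.p_era * x[k]
        return expit(eta)

    blocks = [
        (i, j, k)
        for i in range(S)
        for j in range(J)
        for k in range(K)
        if data.range_mask[i, j] and data.visited[j, k].any()
    ]
    if not blocks:
        return 0.0
    assert len(blocks) <= 14, "instance too large to enumerate"

    # per-block likelihood factor under z = 0 and z = 1
    f0 = np.empty(len(blocks))
    f1 = np.empty(len(blocks))
    for b, (i, j, k) in enumerate(blocks):
        psi, p = psi_of(i, j, k), p_of(j, k)
        lik1, all_zero = psi, True
        for t in range(T):
            if not data.visited[j, k, t]:
                continue
            y = int(data.y[i, j, k, t])
            lik1 *= p if y else (1.0 - p)
            all_zero &= y == 0
        f0[b] = (1.0 - psi) if all_zero else 0.0
        f1[b] = lik1

    total = 0.0
    for config in itertools.product((0, 1), repeat=len(blocks)):
        z = np.array(config, dtype=bool)
        total += float(np.prod(np.where(z, f1, f0)))
    return float(np.log(total))
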