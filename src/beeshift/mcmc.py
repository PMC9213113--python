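"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

A compact, dependency-free implementation of the standard recipe:
leapfrog dynamics on the unconstrained parameter vector, trajectory
doubling until the no-U-turn criterion fires (slice-sampling variant),
warmup split into an initial step-size phase, expanding
variance-estimation windows for the diagonal mass matrix, and a final
step-size phase.  Target densities supply value and gradient jointly as
``logp_grad(theta) -> (float, ndarray)``.

Written for hierarchical occupancy posteriors (hundreds to ~1000
dimensions, cheap vectorized gradients) where an ensemble sampler would
mix far too slowly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSConfig", "sample_nuts", "SamplerRun"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NUTSConfig:
    n_warmup: int = 500
    n_draws: int = 500
    n_chains: int = 2
    max_treedepth: int = 10
    target_accept: float = 0.8
    init_jitter: float = 0.5


@dataclass
class SamplerRun:
    """Draws and per-draw statistics from one `sample_nuts` call."""

    draws: np.ndarray  # (chains, n_draws, dim)
    accept_prob: np.ndarray  # (chains, n_draws)
    tree_depth: np.ndarray  # (chains, n_draws)
    n_divergent: int
    step_size: np.ndarray  # (chains,)


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "grad_prop", "logp_prop",
        "n_valid", "keep_going", "sum_alpha", "n_alpha", "divergent",
    )


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * inv_mass * r_half
    logp, grad_new = logp_grad(theta_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, grad_new, logp


def _joint(logp, r, inv_mass):
    return logp - 0.5 * float(r @ (inv_mass * r))


def _build_tree(logp_grad, theta, r, grad, logu, direction, depth, eps,
                inv_mass, joint0, rng):
    if depth == 0:
        theta1, r1, grad1, logp1 = _leapfrog(
            logp_grad, theta, r, grad, direction * eps, inv_mass
        )
        joint = _joint(logp1, r1, inv_mass)
        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.n_valid = int(logu <= joint)
        t.divergent = (logu - _DIVERGENCE_THRESHOLD) > joint
        t.keep_going = not t.divergent
        t.sum_alpha = float(np.exp(min(0.0, joint - joint0)))
        t.n_alpha = 1
        return t

    t = _build_tree(logp_grad, theta, r, grad, logu, direction, depth - 1,
                    eps, inv_mass, joint0, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.theta_minus, t.r_minus, t.grad_minus,
                             logu, direction, depth - 1, eps, inv_mass,
                             joint0, rng)
            t.theta_minus, t.r_minus, t.grad_minus = (
                t2.theta_minus, t2.r_minus, t2.grad_minus
            )
        else:
            t2 = _build_tree(logp_grad, t.theta_plus, t.r_plus, t.grad_plus,
                             logu, direction, depth - 1, eps, inv_mass,
                             joint0, rng)
            t.theta_plus, t.r_plus, t.grad_plus = (
                t2.theta_plus, t2.r_plus, t2.grad_plus
            )
        total = t.n_valid + t2.n_valid
        if t2.n_valid > 0 and rng.random() < t2.n_valid / total:
            t.theta_prop, t.grad_prop, t.logp_prop = (
                t2.theta_prop, t2.grad_prop, t2.logp_prop
            )
        t.n_valid = total
        t.sum_alpha += t2.sum_alpha
        t.n_alpha += t2.n_alpha
        dtheta = t.theta_plus - t.theta_minus
        no_uturn = (
            float(dtheta @ (inv_mass * t.r_minus)) >= 0
            and float(dtheta @ (inv_mass * t.r_plus)) >= 0
        )
        t.keep_going = t2.keep_going and no_uturn
        t.divergent = t.divergent or t2.divergent
    return t


def _find_initial_step(logp_grad, theta, inv_mass, rng):
    eps = 1.0
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    logp, grad = logp_grad(theta)
    joint0 = _joint(logp, r, inv_mass)
    _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    joint1 = _joint(logp1, r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1 if (joint1 - joint0) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, _, logp1 = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        joint1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


def _warmup_windows(n_warmup: int):
    """(start, end) of the mass-adaptation windows, Stan-style."""
    head = max(int(0.15 * n_warmup), 1)
    tail = max(int(0.1 * n_warmup), 1)
    windows = []
    start, size = head, max((n_warmup - head - tail) // 4, 1)
    while start < n_warmup - tail:
        end = min(start + size, n_warmup - tail)
        # absorb a too-small trailing window
        if (n_warmup - tail - end) < size:
            end = n_warmup - tail
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def _run_chain(logp_grad, theta0, cfg: NUTSConfig, rng):
    dim = theta0.shape[0]
    theta = theta0.copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise FloatingPointError(
            f"non-finite log-density at initialization (logp={logp}); "
            f"theta[:10]={theta[:10]}"
        )
    inv_mass = np.ones(dim)
    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)

    # dual averaging state
    def reset_da(eps):
        return dict(mu=np.log(10.0 * eps), log_eps_bar=0.0, h_bar=0.0, t=0)

    da = reset_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _warmup_windows(cfg.n_warmup)
    win_idx = 0
    wsum = np.zeros(dim)
    wsumsq = np.zeros(dim)
    wn = 0

    n_total = cfg.n_warmup + cfg.n_draws
    draws = np.empty((cfg.n_draws, dim))
    accept = np.empty(cfg.n_draws)
    depths = np.empty(cfg.n_draws, dtype=int)
    n_div = 0

    for it in range(n_total):
        warming = it < cfg.n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, r0, inv_mass)
        logu = joint0 + np.log(rng.random())
        t = _Tree()
        t.theta_minus = t.theta_plus = theta
        t.r_minus = t.r_plus = r0
        t.grad_minus = t.grad_plus = grad
        t.theta_prop, t.grad_prop, t.logp_prop = theta, grad, logp
        t.n_valid, t.keep_going = 1, True
        sum_alpha, n_alpha = 0.0, 0
        depth = 0
        divergent = False
        while t.keep_going and depth < cfg.max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                sub = _build_tree(logp_grad, t.theta_minus, t.r_minus,
                                  t.grad_minus, logu, direction, depth, eps,
                                  inv_mass, joint0, rng)
                t.theta_minus, t.r_minus, t.grad_minus = (
                    sub.theta_minus, sub.r_minus, sub.grad_minus
                )
            else:
                sub = _build_tree(logp_grad, t.theta_plus, t.r_plus,
                                  t.grad_plus, logu, direction, depth, eps,
                                  inv_mass, joint0, rng)
                t.theta_plus, t.r_plus, t.grad_plus = (
                    sub.theta_plus, sub.r_plus, sub.grad_plus
                )
            if sub.keep_going and sub.n_valid > 0:
                if rng.random() < sub.n_valid / max(t.n_valid, 1):
                    t.theta_prop, t.grad_prop, t.logp_prop = (
                        sub.theta_prop, sub.grad_prop, sub.logp_prop
                    )
            t.n_valid += sub.n_valid
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            divergent = divergent or sub.divergent
            dtheta = t.theta_plus - t.theta_minus
            t.keep_going = (
                sub.keep_going
                and float(dtheta @ (inv_mass * t.r_minus)) >= 0
                and float(dtheta @ (inv_mass * t.r_plus)) >= 0
            )
            depth += 1
        theta, grad, logp = t.theta_prop, t.grad_prop, t.logp_prop
        alpha_mean = sum_alpha / max(n_alpha, 1)

        if warming:
            # dual averaging
            da["t"] += 1
            frac = 1.0 / (da["t"] + t0)
            da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (
                cfg.target_accept - alpha_mean
            )
            log_eps = da["mu"] - np.sqrt(da["t"]) / gamma * da["h_bar"]
            w = da["t"] ** -kappa
            da["log_eps_bar"] = w * log_eps + (1 - w) * da["log_eps_bar"]
            eps = float(np.exp(log_eps))
            # mass-matrix windows
            if win_idx < len(windows):
                wstart, wend = windows[win_idx]
                if wstart <= it < wend:
                    wsum += theta
                    wsumsq += theta**2
                    wn += 1
                if it == wend - 1 and wn > 1:
                    var = wsumsq / wn - (wsum / wn) ** 2
                    # regularize towards unit scale (Stan's shrinkage)
                    var = (wn / (wn + 5.0)) * var + (5.0 / (wn + 5.0)) * 1e-3
                    inv_mass = np.maximum(var, 1e-10)
                    wsum[:] = 0.0
                    wsumsq[:] = 0.0
                    wn = 0
                    win_idx += 1
                    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
                    da = reset_da(eps)
            if it == cfg.n_warmup - 1:
                eps = float(np.exp(da["log_eps_bar"]))
        else:
            i = it - cfg.n_warmup
            draws[i] = theta
            accept[i] = alpha_mean
            depths[i] = depth
            n_div += int(divergent)

    return draws, accept, depths, n_div, eps


def sample_nuts(
    logp_grad,
    init: np.ndarray,
    cfg: NUTSConfig,
    seed: int,
) -> SamplerRun:
    """Run `cfg.n_chains` independent NUTS chains.

    ``init`` is a (dim,) centre; each chain starts at
    ``init + jitter * N(0, 1)``.  Fully deterministic given ``seed``.
    """
    seqs = np.random.SeedSequence(seed).spawn(cfg.n_chains)
    all_draws, all_accept, all_depth, all_eps = [], [], [], []
    n_div = 0
    for seq in seqs:
        rng = np.random.default_rng(seq)
        theta0 = init + cfg.init_jitter * rng.standard_normal(init.shape)
        d, a, dep, nd, eps = _run_chain(logp_grad, theta0, cfg, rng)
        all_draws.append(d)
        all_accept.append(a)
        all_depth.append(dep)
        all_eps.append(eps)
        n_div += nd
    return SamplerRun(
        draws=np.stack(all_draws),
        accept_prob=np.stack(all_accept),
        tree_depth=np.stack(all_depth),
        n_divergent=n_div,
        step_size=np.array(all_eps),
    )
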