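"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A self-contained gradient-based sampler used by the model-fitting layer:
leapfrog dynamics with a diagonal mass matrix, dual-averaging step-size
adaptation toward a target acceptance rate, windowed estimation of the mass
matrix from warmup draws, and a jittered fixed integration time in place of
a dynamic termination criterion.  Trajectories whose Hamiltonian error
exceeds a large threshold are counted as divergent and rejected.

The target is supplied as ``logp_grad(x) -> (logp, grad)`` with analytic
gradients; hierarchical models should be non-centered before reaching this
module so the posterior geometry is close to unit scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HmcConfig", "HmcRun", "sample_hmc"]

_DIVERGENCE_THRESHOLD = 1000.0  # Hamiltonian error treated as divergent


@dataclass(frozen=True)
class HmcConfig:
    n_chains: int = 2
    n_warmup: int = 500
    n_draws: int = 500
    target_accept: float = 0.9
    integration_time: float = 1.2   # leapfrog trajectory length (eps * steps)
    max_leapfrog: int = 256
    #: chain-start jitter around ``init``: in posterior-sd units when an
    #: inverse mass is supplied, absolute otherwise
    init_jitter: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_draws) < 1:
            raise ValueError("n_chains, n_warmup and n_draws must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class HmcRun:
    """Raw sampler output: draws of shape (chain, draw, dim) plus stats."""

    draws: np.ndarray
    accept_rate: np.ndarray      # per chain, sampling phase
    divergences: np.ndarray      # per chain, sampling phase
    step_size: np.ndarray        # per chain, post-adaptation
    inv_mass: np.ndarray         # per chain, diagonal


def _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass):
    """Run n_steps of leapfrog; returns (x, p, logp, grad, diverged)."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, -np.inf, grad, True
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, logp, grad, False


def _hamiltonian(logp, p, inv_mass):
    return -logp + 0.5 * float(np.dot(p * inv_mass, p))


def _find_initial_step(logp_grad, x, logp, grad, inv_mass, rng):
    """Crude bracketing heuristic: scale eps until the one-step acceptance
    probability crosses 1/2."""
    eps = 0.1
    sd = np.sqrt(1.0 / inv_mass)
    p = rng.standard_normal(x.size) * sd
    h0 = _hamiltonian(logp, p, inv_mass)

    def accept_logprob(eps):
        x1, p1, logp1, _, div = _leapfrog(logp_grad, x, p, grad, eps, 1, inv_mass)
        if div:
            return -np.inf
        return h0 - _hamiltonian(logp1, p1, inv_mass)

    a = 1.0 if accept_logprob(eps) > np.log(0.5) else -1.0
    for _ in range(50):
        eps_new = eps * 2.0 ** a
        if accept_logprob(eps_new) * a < np.log(0.5) * a:
            break
        eps = eps_new
    else:  # pragma: no cover - pathological target
        pass
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman schedule)."""

    def __init__(self, eps0: float, target: float,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        eta = m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1.0 - eta) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _warmup_schedule(n_warmup: int) -> list:
    """Iteration indices at which the mass matrix is re-estimated."""
    if n_warmup < 60:
        return [n_warmup]  # too short for windows: step size only
    start = int(0.15 * n_warmup)
    end = int(0.9 * n_warmup)
    mid = (start + end) // 2
    return [start, mid, end]


def _run_chain(logp_grad, x0, cfg: HmcConfig, rng: np.random.Generator,
               inv_mass0: np.ndarray | None = None):
    ndim = x0.size
    x = x0.copy()
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("non-finite log probability at the initial point")

    inv_mass = np.ones(ndim) if inv_mass0 is None else inv_mass0.copy()
    eps = _find_initial_step(logp_grad, x, logp, grad, inv_mass, rng)
    da = _DualAveraging(eps, cfg.target_accept)
    boundaries = set(_warmup_schedule(cfg.n_warmup))
    window: list = []

    draws = np.empty((cfg.n_draws, ndim))
    n_accept = 0
    n_div = 0

    total = cfg.n_warmup + cfg.n_draws
    for it in range(total):
        warm = it < cfg.n_warmup
        sd = np.sqrt(1.0 / inv_mass)
        p0 = rng.standard_normal(ndim) * sd
        h0 = _hamiltonian(logp, p0, inv_mass)

        n_steps = max(1, min(cfg.max_leapfrog, int(np.ceil(cfg.integration_time / eps))))
        if n_steps > 1:  # jitter to avoid resonant trajectory lengths
            n_steps = int(rng.integers(max(1, n_steps // 2), n_steps + 1))

        x1, p1, logp1, grad1, div = _leapfrog(
            logp_grad, x, p0, grad, eps, n_steps, inv_mass)
        if div:
            accept_prob = 0.0
        else:
            dh = h0 - _hamiltonian(logp1, p1, inv_mass)
            if dh < -_DIVERGENCE_THRESHOLD:
                div = True
                accept_prob = 0.0
            else:
                accept_prob = float(min(1.0, np.exp(min(0.0, dh))))
        if accept_prob > 0 and rng.random() < accept_prob:
            x, logp, grad = x1, logp1, grad1

        if warm:
            eps = da.update(accept_prob)
            window.append(x.copy())
            if it + 1 in boundaries:
                if len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0, ddof=1)
                    # shrink toward the current mass so a poorly mixing
                    # window cannot destroy a good prior estimate
                    n = len(window)
                    var = n / (n + 5.0) * var + 5.0 / (n + 5.0) * inv_mass
                    inv_mass = np.where(var > 1e-12, var, inv_mass)
                window = []
                eps = _find_initial_step(logp_grad, x, logp, grad, inv_mass, rng)
                da = _DualAveraging(eps, cfg.target_accept)
            if it + 1 == cfg.n_warmup:
                eps = da.adapted
        else:
            draws[it - cfg.n_warmup] = x
            n_accept += accept_prob
            n_div += int(div)

    return draws, n_accept / cfg.n_draws, n_div, eps, inv_mass


def sample_hmc(logp_grad, init, cfg: HmcConfig, seed: int,
               inv_mass: np.ndarray | None = None) -> HmcRun:
    """Sample ``cfg.n_chains`` chains; ``init`` is the shared starting point
    (each chain jitters it independently).  ``inv_mass`` optionally seeds
    the diagonal inverse mass matrix (e.g. from a Hessian at the mode);
    warmup refines it."""
    init = np.asarray(init, dtype=float)
    ndim = init.size
    seeds = np.random.SeedSequence(seed).spawn(cfg.n_chains)

    all_draws = np.empty((cfg.n_chains, cfg.n_draws, ndim))
    acc = np.empty(cfg.n_chains)
    div = np.empty(cfg.n_chains, dtype=int)
    eps_out = np.empty(cfg.n_chains)
    inv_mass_out = np.empty((cfg.n_chains, ndim))
    jitter_scale = (cfg.init_jitter if inv_mass is None
                    else cfg.init_jitter * np.sqrt(inv_mass))
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        x0 = init + jitter_scale * rng.standard_normal(ndim)
        draws, a, d, eps, im = _run_chain(logp_grad, x0, cfg, rng, inv_mass)
        all_draws[c] = draws
        acc[c], div[c], eps_out[c], inv_mass_out[c] = a, d, eps, im
    return HmcRun(draws=all_draws, accept_rate=acc, divergences=div,
                  step_size=eps_out, inv_mass=inv_mass_out)
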