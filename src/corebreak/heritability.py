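"""Multiresolution heritability of root-count intensity profiles.

Heritability is computed on the scale of the log intensity (the
linear-predictor scale of the Poisson model), depth by depth.  Writing

    log theta_ij(t) = psi0 + kappa_j + tau_i + (alpha_i - 1) log t
                      - beta_i t + phi_ijt,

the genotypic variance at depth t is the variance across genotypes of
``tau_i + alpha_i log t - beta_i t``::

    sigma2_genes(t) = sigma_tau^2 + (log t)^2 Var(alpha) + t^2 Var(beta)
                      - 2 t log(t) Cov(alpha, beta)

with Var/Cov the closed-form lognormal moments implied by the bivariate
Gaussian on (log alpha, log beta).  The total (phenotypic) variance on this
scale adds the segment noise: ``sigma2_logtheta(t) = sigma2_genes(t) +
sigma_phi^2``.

Four measures are defined:

* ``overall``          -- sigma2_genes(t) / sigma2_logtheta(t)
* ``tau``              -- sigma_tau^2 / (sigma_tau^2 + sigma_phi^2),
                          depth-free (the near-surface mean count)
* ``alpha_given_beta`` -- (log t)^2 E[Var(alpha | beta)] / sigma2_logtheta(t)
* ``beta_given_alpha`` -- t^2 E[Var(beta | alpha)] / sigma2_logtheta(t)

The component measures use the *conditional* genetic variance so that the
variance shared between the bulk and exploration parameters is attributed
to neither standalone component; by the law of total variance each
component is then bounded by the overall measure, and every value lies in
[0, 1].  Depth-specific values are pooled into a genotype-level summary by
the harmonic mean; the alpha component is exactly zero at t = 1 (log 1 = 0)
and that boundary depth is excluded from its pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PopulationParams

__all__ = [
    "MEASURES",
    "VarianceDecomposition",
    "HeritabilityResult",
    "lognormal_moments",
    "lognormal_cov",
    "conditional_residual_var",
    "variance_decomposition",
    "heritability_curve",
    "pool_harmonic",
    "pooled_heritability",
    "posterior_heritability",
]

MEASURES = ("overall", "tau", "alpha_given_beta", "beta_given_alpha")


def lognormal_moments(mu, sigma):
    """Mean and variance of ``exp(X)`` for ``X ~ N(mu, sigma^2)``.

    mean = exp(mu + sigma^2/2); var = exp(2 mu + sigma^2)(exp(sigma^2) - 1).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    mean = np.exp(mu + 0.5 * sigma ** 2)
    var = np.exp(2.0 * mu + sigma ** 2) * np.expm1(sigma ** 2)
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def lognormal_cov(mu_a, mu_b, sigma_a, sigma_b, rho):
    """Covariance of bivariate-lognormal coordinates.

    ``Cov = exp(mu_a + mu_b + (sigma_a^2 + sigma_b^2)/2)
    (exp(rho sigma_a sigma_b) - 1)``; its sign is the sign of rho.
    """
    mu_a, mu_b = np.asarray(mu_a, float), np.asarray(mu_b, float)
    sigma_a, sigma_b = np.asarray(sigma_a, float), np.asarray(sigma_b, float)
    rho = np.asarray(rho, float)
    if np.any(sigma_a < 0) or np.any(sigma_b < 0):
        raise ValueError("sigmas must be >= 0")
    if np.any(np.abs(rho) > 1):
        raise ValueError("|rho| must be <= 1")
    out = np.exp(mu_a + mu_b + 0.5 * (sigma_a ** 2 + sigma_b ** 2)) \
        * np.expm1(rho * sigma_a * sigma_b)
    return float(out) if out.ndim == 0 else out


def conditional_residual_var(mu_a, sigma_a, rho):
    """Expected conditional variance ``E[Var(alpha | beta)]`` for a
    lognormal coordinate of a bivariate-lognormal pair.

    Equals ``exp(2 mu_a + sigma_a^2)(exp(sigma_a^2) - exp(rho^2
    sigma_a^2))``: the marginal lognormal variance minus the part
    explained by the other coordinate; zero when rho = +/-1.
    """
    mu_a = np.asarray(mu_a, float)
    sigma_a = np.asarray(sigma_a, float)
    rho = np.asarray(rho, float)
    if np.any(sigma_a < 0):
        raise ValueError("sigma must be >= 0")
    if np.any(np.abs(rho) > 1):
        raise ValueError("|rho| must be <= 1")
    out = np.exp(2.0 * mu_a + sigma_a ** 2) * (
        np.exp(sigma_a ** 2) - np.exp(rho ** 2 * sigma_a ** 2)
    )
    out = np.maximum(out, 0.0)  # guard tiny negative round-off at rho ~ 1
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class VarianceDecomposition:
    """Additive decomposition of Var(log theta) at one depth."""

    t: int
    v_tau: float
    v_alpha: float
    v_beta: float
    c_alphabeta: float
    sigma2_genes: float
    sigma2_logtheta: float


def variance_decomposition(pop: PopulationParams, t) -> VarianceDecomposition:
    """Decompose Var(log theta(t)) across genotypes at depth index ``t``.

    v_tau = sigma_tau^2; v_alpha = (log t)^2 Var(alpha);
    v_beta = t^2 Var(beta); c_alphabeta = -2 t log(t) Cov(alpha, beta);
    sigma2_genes is their sum and sigma2_logtheta adds sigma_phi^2.
    """
    t = float(t)
    if t < 1:
        raise ValueError("depth index t must be >= 1")
    _, var_alpha = lognormal_moments(pop.mu_logalpha, pop.sigma_logalpha)
    _, var_beta = lognormal_moments(pop.mu_logbeta, pop.sigma_logbeta)
    cov = lognormal_cov(pop.mu_logalpha, pop.mu_logbeta,
                        pop.sigma_logalpha, pop.sigma_logbeta, pop.rho)
    log_t = np.log(t)
    v_tau = pop.sigma_tau ** 2
    v_alpha = log_t ** 2 * var_alpha
    v_beta = t ** 2 * var_beta
    c_ab = -2.0 * t * log_t * cov
    genes = v_tau + v_alpha + v_beta + c_ab
    genes = max(genes, 0.0)  # exact value is a variance, >= 0
    return VarianceDecomposition(
        t=int(t), v_tau=float(v_tau), v_alpha=float(v_alpha),
        v_beta=float(v_beta), c_alphabeta=float(c_ab),
        sigma2_genes=float(genes),
        sigma2_logtheta=float(genes + pop.sigma_phi ** 2),
    )


def heritability_curve(pop: PopulationParams, measure: str,
                       n_depths: int = 18):
    """Depth-specific heritability ``h2(t)``, t = 1..n_depths.

    Returns an array for the depth-resolved measures; the ``tau`` measure
    has no depth curve and returns the single value
    ``sigma_tau^2 / (sigma_tau^2 + sigma_phi^2)``.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of "
                         f"{MEASURES}")
    if measure == "tau":
        denom = pop.sigma_tau ** 2 + pop.sigma_phi ** 2
        return float(pop.sigma_tau ** 2 / denom) if denom > 0 else 0.0

    t = np.arange(1, n_depths + 1, dtype=float)
    decomp = [variance_decomposition(pop, ti) for ti in t]
    total = np.array([d.sigma2_logtheta for d in decomp])
    with np.errstate(invalid="ignore", divide="ignore"):
        if measure == "overall":
            num = np.array([d.sigma2_genes for d in decomp])
        elif measure == "alpha_given_beta":
            num = np.log(t) ** 2 * conditional_residual_var(
                pop.mu_logalpha, pop.sigma_logalpha, pop.rho)
        else:  # beta_given_alpha
            num = t ** 2 * conditional_residual_var(
                pop.mu_logbeta, pop.sigma_logbeta, pop.rho)
        h2 = np.where(total > 0, num / np.maximum(total, 1e-300), 0.0)
    return np.clip(h2, 0.0, 1.0)


def pool_harmonic(values) -> float:
    """Harmonic mean ``n / sum(1/v)`` of positive depth-specific values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot pool an empty set of values")
    if np.any(values <= 0):
        raise ValueError("harmonic pooling requires strictly positive values")
    return float(values.size / np.sum(1.0 / values))


def _pooling_mask(measure: str, n_depths: int) -> np.ndarray:
    """Depths entering the harmonic pool; t=1 is excluded for the alpha
    component where log(1) = 0 forces an exact zero."""
    mask = np.ones(n_depths, dtype=bool)
    if measure == "alpha_given_beta":
        mask[0] = False
    return mask


def pooled_heritability(pop: PopulationParams, measure: str,
                        n_depths: int = 18) -> float:
    """Genotype-level heritability: harmonic mean over the depth curve.

    For the depth-free ``tau`` measure this is the measure itself.  Returns
    0.0 when any pooled depth value is exactly zero (the harmonic-mean
    limit).
    """
    curve = heritability_curve(pop, measure, n_depths)
    if measure == "tau":
        return float(curve)
    curve = np.asarray(curve)[_pooling_mask(measure, n_depths)]
    if np.any(curve <= 0):
        return 0.0
    return pool_harmonic(curve)


@dataclass(frozen=True)
class HeritabilityResult:
    """Posterior summary of one heritability measure.

    ``curve`` is a tidy table with one row per depth (absent for the
    depth-free tau measure) and one row for the pooled value; columns are
    mean, median and the credible-interval bounds.
    """

    measure: str
    level: float
    curve: pd.DataFrame
    pooled_draws: np.ndarray

    @property
    def pooled_median(self) -> float:
        row = self.curve[self.curve["depth"] == "pooled"].iloc[0]
        return float(row["median"])

    @property
    def pooled_interval(self) -> tuple:
        row = self.curve[self.curve["depth"] == "pooled"].iloc[0]
        return float(row["lower"]), float(row["upper"])


def _pop_from_draw(post_params: dict, s: int, n_blocks: int) -> PopulationParams:
    return PopulationParams(
        psi0=float(post_params["psi0"][s]),
        kappa=tuple([0.0] * n_blocks),  # kappa does not enter heritability
        mu_logalpha=float(post_params["mu_logalpha"][s]),
        mu_logbeta=float(post_params["mu_logbeta"][s]),
        sigma_logalpha=float(post_params["sigma_logalpha"][s]),
        sigma_logbeta=float(post_params["sigma_logbeta"][s]),
        rho=float(np.clip(post_params["rho"][s], -1.0, 1.0)),
        sigma_tau=float(post_params["sigma_tau"][s]),
        sigma_phi=float(post_params["sigma_phi"][s]),
    )


def posterior_heritability(post, measure: str, n_depths: int | None = None,
                           level: float = 0.95) -> HeritabilityResult:
    """Propagate a fitted posterior through the heritability definitions.

    For every draw, the depth curve and its harmonic-mean pooled value are
    computed from that draw's hyper-parameters; the result summarizes the
    draws by mean, median and central credible interval, per depth and for
    the pooled value.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of "
                         f"{MEASURES}")
    required = ("sigma_tau", "sigma_phi", "mu_logalpha", "mu_logbeta",
                "sigma_logalpha", "sigma_logbeta", "rho")
    missing = [k for k in required if k not in post.posterior]
    if missing:
        raise ValueError(
            f"posterior lacks hyper-parameter draws {missing}; "
            "heritability needs a hierarchical-variant fit")
    if n_depths is None:
        n_depths = (post.design.n_depths if post.design is not None
                    else int(post.cells["depth"].max()))

    stacked = {k: post.stacked(k) for k in required + ("psi0",)}
    n_s = stacked["sigma_tau"].shape[0]
    n_blocks = int(post.cells["block"].max())

    if measure == "tau":
        st2 = stacked["sigma_tau"] ** 2
        sp2 = stacked["sigma_phi"] ** 2
        pooled = st2 / (st2 + sp2)
        curves = None
    else:
        curves = np.empty((n_s, n_depths))
        pooled = np.empty(n_s)
        for s in range(n_s):
            pop = _pop_from_draw(stacked, s, n_blocks)
            curves[s] = heritability_curve(pop, measure, n_depths)
            sub = curves[s][_pooling_mask(measure, n_depths)]
            pooled[s] = (pool_harmonic(sub) if np.all(sub > 0) else 0.0)

    lo = (1.0 - level) / 2.0
    rows = []
    if curves is not None:
        for t in range(n_depths):
            col = curves[:, t]
            rows.append({
                "depth": t + 1, "mean": col.mean(),
                "median": float(np.median(col)),
                "lower": float(np.quantile(col, lo)),
                "upper": float(np.quantile(col, 1.0 - lo)),
            })
    rows.append({
        "depth": "pooled", "mean": float(pooled.mean()),
        "median": float(np.median(pooled)),
        "lower": float(np.quantile(pooled, lo)),
        "upper": float(np.quantile(pooled, 1.0 - lo)),
    })
    return HeritabilityResult(measure=measure, level=level,
                              curve=pd.DataFrame(rows), pooled_draws=pooled)
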