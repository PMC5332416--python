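"""Hierarchical nonlinear Poisson mixed model for root-count depth profiles.

Observation model
-----------------
Counts are conditionally Poisson with a plot-specific intensity curve over
the depth index ``t``::

    y_ijkt ~ Poisson(theta_ij(t))
    theta_ij(t) = psi_ij * gamma_{alpha_i, beta_i}(t) * exp(phi_ijt)
    log psi_ij  = psi0 + kappa_j + tau_i

The kernel ``gamma_{a,b}(t) = t**(a-1) * exp(-b*t)`` is proportional to a
gamma probability density: ``alpha`` (the *bulk* parameter) sets the depth
and spread of the densest region of the root system, ``beta`` (the
*exploration* parameter) the rate at which density declines with depth.

Random-effect structure: ``tau_i ~ N(0, sigma_tau^2)`` is the genotypic
deviation of the near-surface mean count (log scale); ``(log alpha_i,
log beta_i)`` are bivariate Gaussian with correlation ``rho`` (so alpha and
beta are bivariate lognormal); ``phi_ijt ~ N(0, sigma_phi^2)`` is a segment
deviation shared by all cores of a plot, which makes the counts
overdispersed relative to Poisson once phi is marginalized.

Identifiability: ``kappa_1 = 0`` (corner constraint); tau and phi have mean
zero by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.special import gammaln

from .data import CoreBreakDataset

__all__ = [
    "VARIANTS",
    "PopulationParams",
    "GenotypeParams",
    "LatentEffects",
    "ModelVariant",
    "PriorSpec",
    "gamma_kernel",
    "log_intensity",
    "log_likelihood",
    "default_priors",
]

#: Recognized model variants: the full hierarchical model, the variant with
#: the bulk-exploration correlation pinned to zero a priori, and the
#: non-hierarchical (unpooled fixed-effects, plain Poisson) counterpart.
VARIANTS = ("model1", "model0_indep", "naive")


@dataclass(frozen=True)
class ModelVariant:
    """Tag selecting one of the comparison models."""

    name: str = "model1"

    def __post_init__(self) -> None:
        if self.name not in VARIANTS:
            raise ValueError(f"unknown model variant {self.name!r}; "
                             f"expected one of {VARIANTS}")

    @property
    def hierarchical(self) -> bool:
        return self.name != "naive"

    @property
    def rho_free(self) -> bool:
        return self.name == "model1"


@dataclass(frozen=True)
class PopulationParams:
    """Study-wide parameters of the hierarchical model.

    ``psi0`` is the study-wide log-intensity intercept, ``kappa`` the fixed
    block shifts (kappa[0] must be 0 by the corner constraint).  The
    remaining fields are the hyper-parameters of the genotype and segment
    random effects.
    """

    psi0: float
    kappa: tuple
    mu_logalpha: float
    mu_logbeta: float
    sigma_logalpha: float
    sigma_logbeta: float
    rho: float
    sigma_tau: float
    sigma_phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", tuple(float(k) for k in self.kappa))
        for name in ("sigma_logalpha", "sigma_logbeta", "sigma_tau", "sigma_phi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.kappa and self.kappa[0] != 0.0:
            raise ValueError("kappa[0] must be 0 (corner constraint)")

    @property
    def n_blocks(self) -> int:
        return len(self.kappa)

    def replace(self, **kwargs) -> "PopulationParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "psi0": self.psi0, "kappa": list(self.kappa),
            "mu_logalpha": self.mu_logalpha, "mu_logbeta": self.mu_logbeta,
            "sigma_logalpha": self.sigma_logalpha,
            "sigma_logbeta": self.sigma_logbeta, "rho": self.rho,
            "sigma_tau": self.sigma_tau, "sigma_phi": self.sigma_phi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(**{**d, "kappa": tuple(d["kappa"])})


@dataclass(frozen=True)
class GenotypeParams:
    """Realized per-genotype triple: intercept deviation and kernel shape."""

    tau: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")


@dataclass(frozen=True)
class LatentEffects:
    """Segment deviations phi indexed (genotype, block, depth); cores within
    a plot-depth cell share the same phi."""

    phi: np.ndarray  # shape (n_genotypes, n_blocks, n_depths)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 3:
            raise ValueError("phi must be a 3-d array (genotype, block, depth)")
        object.__setattr__(self, "phi", phi)


def gamma_kernel(alpha, beta, t):
    """Gamma-density kernel ``t**(alpha-1) * exp(-beta*t)``.

    ``alpha`` is the bulk parameter (gamma shape), ``beta`` the exploration
    parameter (gamma rate); ``t`` is the positive depth index (vectorized).
    For alpha > 1 the continuous-argument kernel peaks at ``(alpha-1)/beta``.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("alpha and beta must be > 0")
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    out = np.exp((alpha - 1.0) * np.log(t) - beta * t)
    return out if out.ndim else float(out)


def log_intensity(pop: PopulationParams, g: GenotypeParams, phi, j: int, t):
    """Log intensity ``log theta_ij(t)`` of one plot-depth cell.

    Equals ``psi0 + kappa_j + tau_i + (alpha_i - 1) log t - beta_i t +
    phi_ijt``; ``j`` is the 1-based block index and ``t`` the 1-based depth
    index (vectorized over t).
    """
    if not 1 <= j <= pop.n_blocks:
        raise ValueError(f"block index {j} outside 1..{pop.n_blocks}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("depth index t must be >= 1")
    out = (pop.psi0 + pop.kappa[j - 1] + g.tau
           + (g.alpha - 1.0) * np.log(t) - g.beta * t + np.asarray(phi, float))
    return out if out.ndim else float(out)


def log_likelihood(
    data: CoreBreakDataset,
    pop: PopulationParams,
    genotypes: list,
    latent: LatentEffects,
):
    """Poisson log likelihood of a dataset given all model parameters.

    Returns ``(total, per_record)`` where ``per_record`` aligns with the
    dataset's (sorted) row order; the per-record vector is the input to
    WAIC.
    """
    df = data.table
    i = df["genotype"].to_numpy() - 1
    j = df["block"].to_numpy() - 1
    t = df["depth"].to_numpy()
    y = df["count"].to_numpy()

    n_g, n_b, n_d = latent.phi.shape
    if i.size and (i.max() >= n_g or j.max() >= n_b or t.max() > n_d):
        raise ValueError("dataset indices exceed the latent-effect dimensions")
    if len(genotypes) < n_g:
        raise ValueError("need one GenotypeParams per genotype")

    tau = np.array([g.tau for g in genotypes])
    alpha = np.array([g.alpha for g in genotypes])
    beta = np.array([g.beta for g in genotypes])
    kappa = np.asarray(pop.kappa)

    log_theta = (pop.psi0 + kappa[j] + tau[i]
                 + (alpha[i] - 1.0) * np.log(t) - beta[i] * t
                 + latent.phi[i, j, t - 1])
    per_record = y * log_theta - np.exp(log_theta) - gammaln(y + 1.0)
    return float(per_record.sum()), per_record


# --- prior specification ----------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for one model variant.

    Normal priors are (mean, sd) pairs; scale parameters get half-normal
    priors with the stated scale; ``rho`` is uniform on [-1, 1] when free.
    The defaults cover the plausible range of kernel shapes (bulk parameter
    of a few units, exploration parameter below ~2) without being sharp.
    """

    variant: ModelVariant
    psi0: tuple = (0.0, 10.0)
    kappa: tuple = (0.0, 10.0)
    mu_logalpha: tuple = (math.log(4.0), 1.5)
    mu_logbeta: tuple = (math.log(0.5), 1.5)
    sd_scale: float = 2.0          # half-normal scale for all SDs
    rho: str | None = "uniform(-1, 1)"
    # naive variant: unpooled per-genotype fixed effects
    intercept: tuple = (0.0, 10.0)
    logalpha: tuple = (math.log(4.0), 1.5)
    logbeta: tuple = (math.log(0.5), 1.5)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["variant"] = self.variant.name
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        variant = ModelVariant(d.pop("variant", "model1"))
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(variant=variant, **kwargs)

    def entries(self) -> dict:
        """Map of parameter name -> prior description for this variant."""
        if self.variant.name == "naive":
            return {
                "intercept": ("normal", self.intercept),
                "logalpha": ("normal", self.logalpha),
                "logbeta": ("normal", self.logbeta),
            }
        out = {
            "psi0": ("normal", self.psi0),
            "kappa": ("normal", self.kappa),
            "mu_logalpha": ("normal", self.mu_logalpha),
            "mu_logbeta": ("normal", self.mu_logbeta),
            "sigma_logalpha": ("halfnormal", self.sd_scale),
            "sigma_logbeta": ("halfnormal", self.sd_scale),
            "sigma_tau": ("halfnormal", self.sd_scale),
            "sigma_phi": ("halfnormal", self.sd_scale),
        }
        if self.variant.rho_free:
            out["rho"] = ("uniform", (-1.0, 1.0))
        else:
            out["rho"] = ("fixed", 0.0)
        return out


def default_priors(variant: ModelVariant | str = "model1") -> PriorSpec:
    """Default weakly informative prior set for a model variant.

    ``model0_indep`` pins rho = 0 a priori; ``naive`` carries priors only
    for its unpooled fixed effects (no variance components).
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    return PriorSpec(variant=variant)
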