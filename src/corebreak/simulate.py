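"""Synthetic core-break field trials with known ground truth.

Since no field dataset ships with the package, this module generates
complete trials from the generative model itself: genotype parameters drawn
from the bivariate-lognormal / Gaussian hyper-distributions, segment noise
phi drawn once per plot-depth cell and shared across cores, and counts drawn
Poisson at the resulting intensity.

Seeding uses one master seed split into independent sub-streams for the
genotype draws, the phi draws, and the Poisson draws, so that e.g. changing
the number of cores does not alter the realized genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import COLUMNS, CoreBreakDataset, DesignConfig
from .model import GenotypeParams, LatentEffects, PopulationParams

__all__ = [
    "DEFAULT_TRUTH",
    "SimulationTruth",
    "draw_genotypes",
    "simulate_dataset",
    "empirical_profiles",
]

#: Ground-truth population used throughout the test-bench: a mid-depth root
#: bulk (alpha ~ 5, beta ~ 0.6 puts the noise-free peak near t = 6-7, i.e.
#: 60-70 cm), moderate genotypic spread, positive bulk-exploration
#: correlation, and enough segment noise to make counts visibly
#: overdispersed.  These values parameterize the simulator only; they are
#: not estimates of anything.
DEFAULT_TRUTH = PopulationParams(
    psi0=1.5,
    kappa=(0.0, 0.2, -0.1, 0.1),
    mu_logalpha=float(np.log(5.0)),
    mu_logbeta=float(np.log(0.6)),
    sigma_logalpha=0.25,
    sigma_logbeta=0.25,
    rho=0.6,
    sigma_tau=0.2,
    sigma_phi=0.35,
)


@dataclass(frozen=True)
class SimulationTruth:
    """Everything that generated a synthetic dataset."""

    pop: PopulationParams
    genotypes: list
    latent: LatentEffects
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "pop": self.pop.to_dict(),
            "genotypes": [
                {"tau": g.tau, "alpha": g.alpha, "beta": g.beta}
                for g in self.genotypes
            ],
            "phi": self.latent.phi.tolist(),
        }


def _substreams(seed: int) -> tuple:
    """Independent generators for (genotypes, phi, poisson counts)."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def draw_genotypes(pop: PopulationParams, n: int, seed_or_rng) -> list:
    """Draw ``n`` genotype triples (tau, alpha, beta) from the population.

    (log alpha, log beta) are bivariate Gaussian with the population means,
    SDs and correlation rho, then exponentiated; tau is centered Gaussian
    with SD sigma_tau.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    z_a = rng.standard_normal(n)
    z_b = rng.standard_normal(n)
    tau = pop.sigma_tau * rng.standard_normal(n)
    log_alpha = pop.mu_logalpha + pop.sigma_logalpha * z_a
    log_beta = pop.mu_logbeta + pop.sigma_logbeta * (
        pop.rho * z_a + np.sqrt(1.0 - pop.rho ** 2) * z_b
    )
    return [
        GenotypeParams(tau=float(tau[i]), alpha=float(np.exp(log_alpha[i])),
                       beta=float(np.exp(log_beta[i])))
        for i in range(n)
    ]


def simulate_dataset(
    pop: PopulationParams,
    design: DesignConfig | None = None,
    seed: int = 0,
    return_truth: bool = False,
    genotypes: list | None = None,
):
    """Simulate a complete core-break trial from the generative model.

    One record per (genotype, block, core, depth); counts are Poisson at
    ``exp(psi0 + kappa_j + tau_i + (alpha_i - 1) log t - beta_i t +
    phi_ijt)`` with phi drawn once per plot-depth cell and shared by the
    cores of that plot.  Pass ``genotypes`` to pin the genotype triples
    instead of drawing them (the genotype sub-stream is still consumed, so
    the phi and count streams are unchanged).

    Returns the dataset, or ``(dataset, SimulationTruth)`` when
    ``return_truth`` is true.
    """
    if design is None:
        design = DesignConfig()
    if pop.n_blocks != design.n_blocks:
        raise ValueError(
            f"pop has {pop.n_blocks} block shifts but design expects "
            f"{design.n_blocks}"
        )
    rng_g, rng_phi, rng_y = _substreams(seed)

    drawn = draw_genotypes(pop, design.n_genotypes, rng_g)
    if genotypes is None:
        genotypes = drawn
    elif len(genotypes) != design.n_genotypes:
        raise ValueError("genotypes must match design.n_genotypes")

    n_g, n_b, n_c, n_d = (design.n_genotypes, design.n_blocks,
                          design.n_cores, design.n_depths)
    phi = pop.sigma_phi * rng_phi.standard_normal((n_g, n_b, n_d))

    tau = np.array([g.tau for g in genotypes])
    alpha = np.array([g.alpha for g in genotypes])
    beta = np.array([g.beta for g in genotypes])
    t = np.arange(1, n_d + 1, dtype=float)

    # (i, j, t) log intensity; cores are conditionally iid given a cell
    log_theta = (
        pop.psi0
        + np.asarray(pop.kappa)[None, :, None]
        + tau[:, None, None]
        + (alpha[:, None, None] - 1.0) * np.log(t)[None, None, :]
        - beta[:, None, None] * t[None, None, :]
        + phi
    )
    theta = np.exp(log_theta)
    counts = rng_y.poisson(np.broadcast_to(theta[:, :, None, :],
                                           (n_g, n_b, n_c, n_d)))

    ii, jj, kk, tt = np.meshgrid(
        np.arange(1, n_g + 1), np.arange(1, n_b + 1),
        np.arange(1, n_c + 1), np.arange(1, n_d + 1), indexing="ij",
    )
    df = pd.DataFrame({
        "genotype": ii.ravel(), "block": jj.ravel(),
        "core": kk.ravel(), "depth": tt.ravel(),
        "count": counts.ravel(),
    })[list(COLUMNS)]
    data = CoreBreakDataset.from_dataframe(df, design)

    if return_truth:
        truth = SimulationTruth(pop=pop, genotypes=list(genotypes),
                                latent=LatentEffects(phi=phi), seed=seed)
        return data, truth
    return data


def empirical_profiles(data: CoreBreakDataset) -> tuple:
    """Mean-count-by-depth tables.

    Returns ``(by_genotype, by_plot)``: the first averages counts over
    blocks and cores per (genotype, depth), the second over cores per
    (genotype, block, depth).  Depths with no records appear as NaN in the
    pivoted tables.
    """
    df = data.table
    by_genotype = (
        df.groupby(["genotype", "depth"])["count"].mean()
        .unstack("depth")
    )
    by_plot = (
        df.groupby(["genotype", "block", "depth"])["count"].mean()
        .unstack("depth")
    )
    return by_genotype, by_plot
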