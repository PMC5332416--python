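# Methods

## The model

Core-break data are long tables of root counts `y_ijkt` for genotype `i`,
block `j`, core `k` and depth segment `t` (1-based index; physical depth is
`t × 10 cm` by default). The package models these counts as conditionally
Poisson around a smooth genotype-specific intensity curve over depth:

    y_ijkt | theta_ij(t)  ~  Poisson(theta_ij(t))
    theta_ij(t) = psi_ij · gamma_{alpha_i, beta_i}(t) · exp(phi_ijt)
    log psi_ij  = psi0 + kappa_j + tau_i
    gamma_{a,b}(t) = t^(a-1) · exp(-b·t)

The kernel is proportional to a gamma probability density. `alpha` (the
*bulk* parameter) controls where the root system is densest and how spread
out that region is; `beta` (the *exploration* parameter) controls how fast
density declines with depth — a smaller `beta` means a fatter tail, i.e. a
root system that keeps exploring downward. For `alpha > 1` the
continuous-argument kernel peaks at `(alpha − 1)/beta` depth units.

Random-effect structure:

* `tau_i ~ N(0, sigma_tau²)` — genotypic deviation of the near-surface
  mean count (log scale);
* `(log alpha_i, log beta_i)` — bivariate Gaussian with means
  `mu_logalpha`, `mu_logbeta`, SDs `sigma_logalpha`, `sigma_logbeta` and
  correlation `rho`, so `(alpha, beta)` are bivariate lognormal;
* `phi_ijt ~ N(0, sigma_phi²)` — a segment-level deviation drawn once per
  plot–depth cell and shared by all cores of that plot. Marginally over
  `phi` the counts are overdispersed relative to Poisson, which is the
  behavior core-break counts show in the field.

Identifiability: `kappa_1 = 0` (corner constraint) and `tau`, `phi` have
mean zero by construction; `psi0` and `kappa_j` are fixed effects.

Three variants are implemented: `model1` (full model, `rho` free),
`model0_indep` (`rho` pinned to 0 a priori) and `naive` (per-genotype
unpooled fixed effects `(intercept_i, alpha_i, beta_i)`, no random terms,
plain Poisson likelihood — the non-hierarchical counterpart used as a WAIC
baseline).

### Priors

Weakly informative throughout: `psi0, kappa_j ~ N(0, 10²)`;
`mu_logalpha ~ N(log 4, 1.5²)`; `mu_logbeta ~ N(log 0.5, 1.5²)`; every SD
half-normal with scale 2; `rho ~ Uniform(−1, 1)`. These cover kernels
peaking anywhere from the first segment to far below the sampled window
without concentrating on any of them. The naive variant gets the analogous
normal priors on its unpooled coordinates.

## Heritability

Heritability is defined on the log-intensity (linear-predictor) scale,
depth by depth. Since `log theta` is linear in `tau_i`, `alpha_i log t`
and `−beta_i t`, the genotypic variance at depth `t` has the closed form

    sigma²_genes(t) = sigma_tau² + (log t)²·Var(alpha) + t²·Var(beta)
                      − 2·t·log(t)·Cov(alpha, beta)

with `Var`/`Cov` the exact lognormal moments implied by the hyper-
parameters, and `sigma²_logtheta(t) = sigma²_genes(t) + sigma_phi²`. Four
measures are computed:

| measure            | numerator at depth t                        |
|--------------------|---------------------------------------------|
| `overall`          | `sigma²_genes(t)`                            |
| `tau`              | `sigma_tau²` (depth-free)                    |
| `alpha_given_beta` | `(log t)² · E[Var(alpha | beta)]`            |
| `beta_given_alpha` | `t² · E[Var(beta | alpha)]`                  |

each divided by `sigma²_logtheta(t)` (the `tau` measure by
`sigma_tau² + sigma_phi²`). The component measures use the *conditional*
genetic variance `E[Var(alpha|beta)] = e^{2mu+sigma²}(e^{sigma²} −
e^{rho²sigma²})`, attributing the variance shared between the bulk and
exploration parameters to neither standalone component; by the law of
total variance each component is then bounded by the overall measure, and
every value lies in [0, 1] for any valid parameter set.

Depth-specific values are pooled to a single genotype-level number by the
harmonic mean over the depth grid. The `alpha` component is identically
zero at `t = 1` (`log 1 = 0` is a boundary artifact of the index
convention, not a biological statement), which would force any harmonic
mean through zero; that single depth is excluded from its pooling and the
exclusion is part of the measure's definition here. Posterior uncertainty
is propagated by recomputing curve and pooled value per posterior draw of
the hyper-parameters and summarizing with medians and central 95%
intervals.

## Inference

The posterior is sampled with an adaptive Hamiltonian Monte Carlo sampler
written for this package (no gradient-based probabilistic-programming
backend is a dependency): leapfrog dynamics with a diagonal mass matrix,
dual-averaging step-size adaptation to a 0.9 target acceptance rate,
windowed re-estimation of the mass during warmup, and a jittered fixed
integration time of 1.2 mass-rescaled units in place of a dynamic
termination criterion. Trajectories with Hamiltonian error above 1000 nats
count as divergences and are rejected. All model gradients are analytic
and are verified against finite differences in the test suite; the sampler
itself is verified on Gaussian targets with known moments and
cross-checked against an independent affine-invariant ensemble sampler on
the naive-variant posterior.

Two details matter for this posterior's geometry:

* **Parameterization.** The sampler runs in the *centered*
  parameterization — the natural effects `eta_i = psi0 + tau_i`,
  `log alpha_i`, `log beta_i`, `phi_ijt` are sampled directly, with the
  hyper-parameters entering only through the hierarchical priors. With
  count data this informative, every effect is pinned by its own
  likelihood term, and the non-centered alternative (standardized deviates
  scaled by the hyper-parameters) creates long hyper-mean ridges that a
  diagonal-mass sampler cannot traverse. Folding `psi0` into the genotype
  intercepts `eta_i` removes the last global ridge; `psi0` is recovered as
  the hyper-mean of `eta`.
* **Initialization.** Chains start at a posterior mode with the mass
  matrix seeded by the Hessian diagonal there. The mode search first fits
  the naive model per genotype (small and well conditioned), assembles the
  hierarchical point from those estimates and their sample moments, and
  refines it by L-BFGS in the *non-centered* geometry — whose mode is
  proper, whereas the centered density is unbounded as any SD tends to
  zero. Without the naive first stage, a generic start can converge into a
  distinct local basin in which the kernel is flat and the segment noise
  absorbs the entire depth trend.

Convergence is reported per scalar hyper-parameter via split R-hat and
bulk effective sample size (computed with arviz); a fit warns when any
R-hat exceeds 1.01 or any divergence occurred. Default run lengths
(2 chains × 500 warmup + 500 draws) are sized for the package's synthetic
designs; the test suite uses 250–400 per phase, which keeps a reduced
design fit at roughly ten seconds on one CPU.

## Profiles, WAIC, residuals

Credible bands for the idealized profile `psi_ij·gamma_i(t)` (segment
noise excluded) and the plot intensity `theta_ij(t)` (included) are
depth-wise posterior quantile envelopes — type-7 (linear-interpolation)
quantiles of the draw values at each depth, not simultaneous bands. Band
overlap uses closed intervals, a conservative reading of "the bands do not
overlap". One non-obvious behavior: with count-rich cells the posterior of
`phi` is pinned by the data and anti-correlated with the idealized curve
(the two sum to a well-determined cell log-intensity), so the intensity
band is not necessarily wider than the idealized band; the familiar
ordering re-emerges when cells are sparse and `phi` stays prior-dominated.

WAIC is computed from the per-record log-likelihood draws as
`waic = −2(lppd − p_waic)` with a stabilized log-mean-exp and the
sample-variance (ddof = 1) penalty; the implementation is checked to
machine precision against a brute-force evaluation and against arviz
(which uses the population variance — the tests account for the ddof
difference exactly).

Model checking uses randomized quantile residuals for the Poisson at the
posterior-mean intensity per record. Because these are in-sample and the
fitted per-cell `phi` tracks each cell's mean, their variance under a
correct model is about `1 − 1/n_cores`, not 1 — with two cores per plot a
strict normality test will reject on large samples even for perfectly
specified data. They are useful for spotting gross misfit and for
comparing variants, and the conditioning shrinkage should be kept in mind
when reading them; the formal normality check in the test suite runs at a
sample size where the artifact is negligible.

## The synthetic-data generator

No field dataset ships with the package, so all analyses run on synthetic
trials drawn from the generative model itself. The default design is 20
genotypes × 4 blocks × 4 cores × 18 depth increments of 10 cm (5 760
records; 288 per genotype, 320 per depth). The default ground-truth
population is

    psi0 = 1.5, kappa = (0, 0.2, −0.1, 0.1),
    mu_logalpha = log 5, mu_logbeta = log 0.6,
    sigma_logalpha = sigma_logbeta = 0.25, rho = 0.6,
    sigma_tau = 0.2, sigma_phi = 0.35

— a mid-depth bulk (noise-free peak near 60–70 cm), moderate genotypic
spread, positive bulk–exploration coupling and visible overdispersion.
These values parameterize the simulator only and are not estimates of any
real trial. Seeding uses one master seed split into independent
sub-streams for genotype draws, segment-noise draws and Poisson draws, so
changing the number of cores does not alter the realized genotypes.

What the generator emulates: the nested design, shared segment noise
within a plot–depth cell, lognormal genotype parameters, Poisson counting
noise, and (optionally) missing segments on read. What it does not:
within-core autocorrelation of the segment noise over depth, spatial
correlation across field plots, soil-structure covariates, or any
image-acquisition artifacts. Passing tests therefore demonstrate that the
estimation machinery recovers the generating process under the model's
own assumptions — not that real core-break data satisfy those
assumptions.

Test and script problem sizes are deliberate choices for a single-CPU
workflow: parameter-recovery runs use 12 genotypes × 4 blocks × 2 cores ×
12 depths with 2 × 400 + 400 chains, the WAIC comparison 6 × 2 × 2 × 8,
and the band-separation experiment two pinned genotypes with well
separated kernels (`(alpha, beta)` of `(3, 0.9)` vs `(8, 0.45)`). At
those sizes the 95% posterior intervals covered the true pooled overall
heritability in 9 of 10 replicate seeds and the true `sigma_phi` in 10 of
10, the hierarchical model beat the naive one on WAIC in 5 of 5, and the
two contrasting genotypes' 95% idealized bands were disjoint at every
depth — all recomputed, not asserted, by the test suite and
`scripts/acceptance.py`.

## Numerical choices and edge cases

* `log theta` is capped at ±100 during sampling; states beyond it are
  treated as divergent rather than evaluated (`exp` would overflow well
  before any plausible intensity).
* `rho` is sampled as `atanh(rho)` with the uniform prior's Jacobian; the
  closed-form `E[Var(alpha|beta)]` clips tiny negative round-off at
  `|rho| → 1` to zero.
* `sigma²_genes(t)` is mathematically a variance and is floored at zero
  against round-off in the cancellation between the `t²` and covariance
  terms.
* Harmonic pooling requires strictly positive inputs; a zero depth value
  (possible only at excluded boundaries or degenerate parameter sets)
  yields a pooled value of exactly zero rather than an error in the
  posterior path.
* Quantiles everywhere are numpy's default type-7 linear interpolation,
  making bands deterministic given draws.
* Missing plot–depth cells are allowed in datasets (the likelihood skips
  them); intensity-profile bands require every depth of the requested
  plot observed and say so otherwise.

## Known limitations

* The sampler's fixed-integration-time trajectories mix the variance
  hyper-parameters more slowly than a dynamic-termination sampler would;
  short chains can under-explore the upper tails of `sigma_logbeta` in
  particular. Diagnostics expose this (ESS per parameter), and longer
  chains resolve it.
* Kernel parameters of genotypes whose peak lies below the sampled depth
  window are weakly identified (the data never see the curve turn over);
  their posteriors are legitimately wide and prior-influenced.
* WAIC is the only predictive criterion implemented; no cross-validation
  alternative is provided.
* Heritability here is a broad-sense, model-based quantity on the
  log-intensity scale; it is not comparable to classical REML/ANOVA
  estimators on the count scale.
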