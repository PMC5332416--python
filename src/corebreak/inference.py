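"""Posterior inference for the hierarchical root-count model.

This module turns a dataset into an unconstrained log-posterior with
analytic gradients (non-centered parameterization of every random effect),
samples it with the adaptive HMC sampler, and exposes the posterior
summaries the analysis needs: idealized and plot-specific intensity
profiles with depth-wise credible bands, WAIC model comparison, and
randomized quantile residuals.

Likelihood bookkeeping exploits the fact that all cores of a plot share one
intensity per depth: records are grouped into (genotype, block, depth)
cells with sufficient statistics (n, sum y), so a log-posterior evaluation
is O(number of cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data import CoreBreakDataset, DesignConfig
from .model import ModelVariant, PriorSpec, default_priors
from .sampler import HmcConfig, sample_hmc

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "ProfileBand",
    "OverlapResult",
    "WaicResult",
    "fit",
    "idealized_profile",
    "intensity_profile",
    "band_overlap",
    "waic",
    "waic_from_matrix",
    "quantile_residuals",
]

_LOGTHETA_CAP = 100.0  # beyond this the state is treated as divergent


def _quiet(func):
    """Silence overflow/invalid warnings inside a log-posterior evaluation;
    non-finite states are handled explicitly and rejected by the sampler."""
    import functools

    @functools.wraps(func)
    def wrapper(*args, **kwargs):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return func(*args, **kwargs)

    return wrapper


@dataclass(frozen=True)
class McmcConfig:
    """Sampler run lengths and tuning."""

    n_chains: int = 2
    n_warmup: int = 500
    n_draws: int = 500
    seed: int = 0
    target_accept: float = 0.9

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_draws) < 1:
            raise ValueError("chain, warmup and draw counts must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


# --------------------------------------------------------------------------
# compiled likelihood: cell bookkeeping shared by all variants


class _Cells:
    """Sufficient statistics per (genotype, block, depth) cell."""

    def __init__(self, data: CoreBreakDataset):
        df = data.table
        if len(df) == 0:
            raise ValueError("cannot fit an empty dataset")
        grouped = (
            df.groupby(["genotype", "block", "depth"], sort=True)["count"]
            .agg(["size", "sum"]).reset_index()
        )
        self.frame = grouped.rename(columns={"size": "n", "sum": "sum_y"})
        self.i = grouped["genotype"].to_numpy() - 1      # 0-based
        self.j = grouped["block"].to_numpy() - 1
        self.t = grouped["depth"].to_numpy().astype(float)  # 1-based value
        self.n = grouped["size"].to_numpy().astype(float)
        self.sum_y = grouped["sum"].to_numpy().astype(float)
        self.log_t = np.log(self.t)
        self.n_cells = len(grouped)

        key = list(zip(self.i, self.j, self.t.astype(int)))
        lookup = {c: s for s, c in enumerate(key)}
        rec = df[["genotype", "block", "depth"]].to_numpy()
        self.rec_cell = np.array(
            [lookup[(r[0] - 1, r[1] - 1, r[2])] for r in rec]
        )
        self.rec_y = df["count"].to_numpy().astype(float)
        self.rec_lgamma = gammaln(self.rec_y + 1.0)

        self.n_genotypes = int(df["genotype"].max())
        self.n_blocks = int(df["block"].max())
        self.n_depths = int(df["depth"].max())


class _HierModel:
    """Unconstrained parameterization of the hierarchical variants.

    Layout: psi0 | kappa[2..nB] | mu_la | mu_lb | u_la | u_lb | (zr) |
    u_tau | u_phi | tau (nG) | a (nG) | b (nG) | phi (n_cells), where u_*
    are log SDs and zr = atanh(rho) when the correlation is free.

    Two parameterizations of the random-effect blocks are supported.
    *Centered* (the sampling default): the blocks are the natural effects
    with their hierarchical Gaussian priors — the genotype intercept block
    holds ``eta_i = psi0 + tau_i`` (with prior ``N(psi0, sigma_tau^2)``,
    so psi0 appears in the likelihood only through eta), and the kernel
    blocks hold (log alpha_i, log beta_i) and phi_ijt directly.  This is
    the well-conditioned geometry when the counts are informative: each
    effect is pinned by its own likelihood term instead of riding a
    hyper-mean ridge.  *Non-centered*: the blocks are standardized
    deviates z with N(0,1) priors, scaled and shifted by the
    hyper-parameters; this geometry has a proper posterior mode and is
    used for the MAP initialization.
    """

    def __init__(self, cells: _Cells, priors: PriorSpec,
                 centered: bool = True):
        self.cells = cells
        self.priors = priors
        self.centered = centered
        self.rho_free = priors.variant.rho_free
        nG, nB = cells.n_genotypes, cells.n_blocks
        self.nG, self.nB = nG, nB

        sizes = [1, nB - 1, 1, 1, 1, 1]
        names = ["psi0", "kappa_free", "mu_la", "mu_lb", "u_la", "u_lb"]
        if self.rho_free:
            sizes.append(1)
            names.append("zr")
        sizes += [1, 1, nG, nG, nG, cells.n_cells]
        names += ["u_tau", "u_phi", "tau", "a", "b", "phi"]
        self.slices = {}
        off = 0
        for nm, sz in zip(names, sizes):
            self.slices[nm] = slice(off, off + sz)
            off += sz
        self.ndim = off

    # -- packing helpers ---------------------------------------------------

    def _split(self, x: np.ndarray) -> dict:
        return {nm: x[..., sl] for nm, sl in self.slices.items()}

    def init_point(self) -> np.ndarray:
        c = self.cells
        x = np.zeros(self.ndim)
        p = self.priors
        mu_la0, mu_lb0 = p.mu_logalpha[0], p.mu_logbeta[0]
        a0, b0 = np.exp(mu_la0), np.exp(mu_lb0)
        kernel_mean = float(np.mean((a0 - 1.0) * c.log_t - b0 * c.t))
        ybar = float(c.sum_y.sum() / c.n.sum())
        x[self.slices["psi0"]] = np.log(ybar + 0.5) - kernel_mean
        x[self.slices["mu_la"]] = mu_la0
        x[self.slices["mu_lb"]] = mu_lb0
        for nm in ("u_la", "u_lb", "u_tau", "u_phi"):
            x[self.slices[nm]] = np.log(0.3)
        if self.centered:  # effects at their conditional prior means
            x[self.slices["tau"]] = x[self.slices["psi0"]]
            x[self.slices["a"]] = mu_la0
            x[self.slices["b"]] = mu_lb0
        return x

    # -- log posterior and gradient ----------------------------------------

    def _hypers(self, v: dict):
        psi0 = v["psi0"][0]
        mu_la, mu_lb = v["mu_la"][0], v["mu_lb"][0]
        s_la, s_lb = np.exp(v["u_la"][0]), np.exp(v["u_lb"][0])
        s_tau, s_phi = np.exp(v["u_tau"][0]), np.exp(v["u_phi"][0])
        rho = np.tanh(v["zr"][0]) if self.rho_free else 0.0
        return psi0, mu_la, mu_lb, s_la, s_lb, s_tau, s_phi, rho

    @_quiet
    def logp_grad(self, x: np.ndarray):
        c = self.cells
        v = self._split(x)
        psi0, mu_la, mu_lb, s_la, s_lb, s_tau, s_phi, rho = self._hypers(v)
        kappa = np.concatenate([[0.0], v["kappa_free"]])
        root = np.sqrt(1.0 - rho ** 2)

        if self.centered:
            eta, log_alpha, log_beta, phi = v["tau"], v["a"], v["b"], v["phi"]
        else:
            eta = psi0 + s_tau * v["tau"]
            log_alpha = mu_la + s_la * v["a"]
            log_beta = mu_lb + s_lb * (rho * v["a"] + root * v["b"])
            phi = s_phi * v["phi"]
        alpha = np.exp(log_alpha)
        beta = np.exp(log_beta)

        log_theta = (eta[c.i] + kappa[c.j]
                     + (alpha[c.i] - 1.0) * c.log_t - beta[c.i] * c.t + phi)
        if (not np.isfinite(log_theta).all()
                or np.abs(log_theta).max() > _LOGTHETA_CAP):
            return -np.inf, np.zeros(self.ndim)
        theta = np.exp(log_theta)

        loglik = float(np.sum(c.sum_y * log_theta - c.n * theta))

        pr = self.priors
        logp = loglik
        logp += _normal_logpdf(psi0, *pr.psi0)
        logp += float(np.sum(_normal_logpdf(v["kappa_free"], *pr.kappa)))
        logp += _normal_logpdf(mu_la, *pr.mu_logalpha)
        logp += _normal_logpdf(mu_lb, *pr.mu_logbeta)
        # half-normal on each SD, plus the log-Jacobian of sigma = exp(u)
        sc2 = pr.sd_scale ** 2
        for s, u in ((s_la, v["u_la"][0]), (s_lb, v["u_lb"][0]),
                     (s_tau, v["u_tau"][0]), (s_phi, v["u_phi"][0])):
            logp += -0.5 * s ** 2 / sc2 + u
        if self.rho_free:
            logp += np.log1p(-rho ** 2)  # uniform rho through tanh

        # gradient: g = d loglik / d log_theta per cell
        g = c.sum_y - c.n * theta
        grad = np.zeros(self.ndim)
        gj = np.bincount(c.j, weights=g, minlength=self.nB)
        grad[self.slices["kappa_free"]] = (
            gj[1:] - (v["kappa_free"] - pr.kappa[0]) / pr.kappa[1] ** 2
        )
        gi = np.bincount(c.i, weights=g, minlength=self.nG)          # d/d tau_i
        d_alpha = np.bincount(c.i, weights=g * c.log_t, minlength=self.nG)
        d_beta = -np.bincount(c.i, weights=g * c.t, minlength=self.nG)
        d_la = d_alpha * alpha            # d loglik / d log_alpha_i
        d_lb = d_beta * beta              # d loglik / d log_beta_i

        if self.centered:
            # hierarchical Gaussian priors on the natural effects
            dev = eta - psi0
            da = (log_alpha - mu_la) / s_la
            db = (log_beta - mu_lb) / s_lb
            r2 = 1.0 - rho ** 2
            quad = (da ** 2 - 2.0 * rho * da * db + db ** 2) / r2
            logp += -0.5 * float(quad.sum()) \
                - self.nG * (np.log(s_la) + np.log(s_lb) + 0.5 * np.log(r2)) \
                - self.nG * np.log(2.0 * np.pi)
            logp += -0.5 * float(dev @ dev) / s_tau ** 2 \
                - self.nG * (np.log(s_tau) + 0.5 * np.log(2.0 * np.pi))
            logp += -0.5 * float(phi @ phi) / s_phi ** 2 \
                - phi.size * (np.log(s_phi) + 0.5 * np.log(2.0 * np.pi))

            grad[self.slices["psi0"]] = (
                float(dev.sum()) / s_tau ** 2
                - (psi0 - pr.psi0[0]) / pr.psi0[1] ** 2
            )
            grad[self.slices["tau"]] = gi - dev / s_tau ** 2
            grad[self.slices["phi"]] = g - phi / s_phi ** 2
            grad[self.slices["a"]] = d_la - (da - rho * db) / (r2 * s_la)
            grad[self.slices["b"]] = d_lb - (db - rho * da) / (r2 * s_lb)
            grad[self.slices["mu_la"]] = (
                float(np.sum(da - rho * db)) / (r2 * s_la)
                - (mu_la - pr.mu_logalpha[0]) / pr.mu_logalpha[1] ** 2
            )
            grad[self.slices["mu_lb"]] = (
                float(np.sum(db - rho * da)) / (r2 * s_lb)
                - (mu_lb - pr.mu_logbeta[0]) / pr.mu_logbeta[1] ** 2
            )
            grad[self.slices["u_la"]] = (
                float(np.sum(da ** 2 - rho * da * db)) / r2 - self.nG
                - s_la ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_lb"]] = (
                float(np.sum(db ** 2 - rho * da * db)) / r2 - self.nG
                - s_lb ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_tau"]] = (
                float(dev @ dev) / s_tau ** 2 - self.nG
                - s_tau ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_phi"]] = (
                float(phi @ phi) / s_phi ** 2 - phi.size
                - s_phi ** 2 / sc2 + 1.0
            )
            if self.rho_free:
                d_rho = float(np.sum(
                    da * db * (1.0 + rho ** 2) - rho * (da ** 2 + db ** 2)
                )) / r2 ** 2
                d_rho += self.nG * rho / r2          # -nG/2 log(1-rho^2)
                d_rho += -2.0 * rho / r2             # uniform prior Jacobian
                grad[self.slices["zr"]] = d_rho * r2
        else:
            z_tau, z_a, z_b, z_phi = v["tau"], v["a"], v["b"], v["phi"]
            logp += -0.5 * float(z_tau @ z_tau + z_a @ z_a + z_b @ z_b
                                 + z_phi @ z_phi)
            logp += -0.5 * (3 * self.nG + z_phi.size) * np.log(2.0 * np.pi)

            grad[self.slices["psi0"]] = (
                g.sum() - (psi0 - pr.psi0[0]) / pr.psi0[1] ** 2
            )
            grad[self.slices["mu_la"]] = (
                d_la.sum()
                - (mu_la - pr.mu_logalpha[0]) / pr.mu_logalpha[1] ** 2
            )
            grad[self.slices["mu_lb"]] = (
                d_lb.sum()
                - (mu_lb - pr.mu_logbeta[0]) / pr.mu_logbeta[1] ** 2
            )
            grad[self.slices["a"]] = s_la * d_la + s_lb * rho * d_lb - z_a
            grad[self.slices["b"]] = s_lb * root * d_lb - z_b
            grad[self.slices["tau"]] = s_tau * gi - z_tau
            grad[self.slices["phi"]] = s_phi * g - z_phi

            grad[self.slices["u_la"]] = (
                s_la * float(d_la @ z_a) - s_la ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_lb"]] = (
                s_lb * float(d_lb @ (rho * z_a + root * z_b))
                - s_lb ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_tau"]] = (
                s_tau * float(gi @ z_tau) - s_tau ** 2 / sc2 + 1.0
            )
            grad[self.slices["u_phi"]] = (
                s_phi * float(g @ z_phi) - s_phi ** 2 / sc2 + 1.0
            )
            if self.rho_free:
                d_rho = s_lb * float(d_lb @ (z_a - (rho / root) * z_b))
                d_rho += -2.0 * rho / (1.0 - rho ** 2)  # prior Jacobian
                grad[self.slices["zr"]] = d_rho * (1.0 - rho ** 2)
        return logp, grad

    def logp(self, x: np.ndarray) -> float:
        return self.logp_grad(x)[0]

    def to_centered(self, x: np.ndarray) -> np.ndarray:
        """Map a non-centered point to the equivalent centered point."""
        v = self._split(x)
        psi0, mu_la, mu_lb, s_la, s_lb, s_tau, s_phi, rho = self._hypers(v)
        root = np.sqrt(1.0 - rho ** 2)
        out = x.copy()
        out[self.slices["tau"]] = psi0 + s_tau * v["tau"]
        out[self.slices["a"]] = mu_la + s_la * v["a"]
        out[self.slices["b"]] = mu_lb + s_lb * (rho * v["a"] + root * v["b"])
        out[self.slices["phi"]] = s_phi * v["phi"]
        return out

    def to_noncentered(self, x: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_centered` (hyper-parameters unchanged)."""
        v = self._split(x)
        psi0, mu_la, mu_lb, s_la, s_lb, s_tau, s_phi, rho = self._hypers(v)
        root = np.sqrt(1.0 - rho ** 2)
        out = x.copy()
        out[self.slices["tau"]] = (v["tau"] - psi0) / s_tau
        z_a = (v["a"] - mu_la) / s_la
        out[self.slices["a"]] = z_a
        out[self.slices["b"]] = ((v["b"] - mu_lb) / s_lb - rho * z_a) / root
        out[self.slices["phi"]] = v["phi"] / s_phi
        return out

    # -- posterior transformation -------------------------------------------

    def constrain(self, draws: np.ndarray) -> dict:
        """Map unconstrained draws (..., ndim) to named natural parameters."""
        v = self._split(draws)
        s_la = np.exp(v["u_la"][..., 0])
        s_lb = np.exp(v["u_lb"][..., 0])
        s_tau = np.exp(v["u_tau"][..., 0])
        s_phi = np.exp(v["u_phi"][..., 0])
        rho = (np.tanh(v["zr"][..., 0]) if self.rho_free
               else np.zeros(draws.shape[:-1]))
        root = np.sqrt(1.0 - rho ** 2)
        mu_la = v["mu_la"][..., 0]
        mu_lb = v["mu_lb"][..., 0]
        if self.centered:
            tau = v["tau"] - v["psi0"]
            log_alpha = v["a"]
            log_beta = v["b"]
            phi = v["phi"]
        else:
            tau = s_tau[..., None] * v["tau"]
            log_alpha = mu_la[..., None] + s_la[..., None] * v["a"]
            log_beta = mu_lb[..., None] + s_lb[..., None] * (
                rho[..., None] * v["a"] + root[..., None] * v["b"]
            )
            phi = s_phi[..., None] * v["phi"]
        kappa = np.concatenate(
            [np.zeros(draws.shape[:-1] + (1,)), v["kappa_free"]], axis=-1
        )
        return {
            "psi0": v["psi0"][..., 0],
            "kappa": kappa,
            "mu_logalpha": mu_la, "mu_logbeta": mu_lb,
            "sigma_logalpha": s_la, "sigma_logbeta": s_lb,
            "rho": rho, "sigma_tau": s_tau, "sigma_phi": s_phi,
            "tau": tau, "alpha": np.exp(log_alpha), "beta": np.exp(log_beta),
            "phi": phi,
        }

    def cell_log_theta(self, params: dict) -> np.ndarray:
        """Per-draw log intensity of every cell; params from ``constrain``."""
        c = self.cells
        kappa = params["kappa"][..., c.j]
        tau = params["tau"][..., c.i]
        alpha = params["alpha"][..., c.i]
        beta = params["beta"][..., c.i]
        return (params["psi0"][..., None] + kappa + tau
                + (alpha - 1.0) * c.log_t - beta * c.t + params["phi"])


class _NaiveModel:
    """Unpooled fixed-effects Poisson model: per-genotype intercept and
    kernel parameters, no random terms.  Layout: intercept (nG) |
    log_alpha (nG) | log_beta (nG)."""

    def __init__(self, cells: _Cells, priors: PriorSpec):
        self.cells = cells
        self.priors = priors
        nG = cells.n_genotypes
        self.nG = nG
        self.slices = {
            "intercept": slice(0, nG),
            "log_alpha": slice(nG, 2 * nG),
            "log_beta": slice(2 * nG, 3 * nG),
        }
        self.ndim = 3 * nG

    def init_point(self) -> np.ndarray:
        c = self.cells
        p = self.priors
        x = np.zeros(self.ndim)
        a0, b0 = np.exp(p.logalpha[0]), np.exp(p.logbeta[0])
        kernel_mean = float(np.mean((a0 - 1.0) * c.log_t - b0 * c.t))
        ybar = float(c.sum_y.sum() / c.n.sum())
        x[self.slices["intercept"]] = np.log(ybar + 0.5) - kernel_mean
        x[self.slices["log_alpha"]] = p.logalpha[0]
        x[self.slices["log_beta"]] = p.logbeta[0]
        return x

    @_quiet
    def logp_grad(self, x: np.ndarray):
        c = self.cells
        inter = x[self.slices["intercept"]]
        log_alpha = x[self.slices["log_alpha"]]
        log_beta = x[self.slices["log_beta"]]
        alpha, beta = np.exp(log_alpha), np.exp(log_beta)

        log_theta = (inter[c.i] + (alpha[c.i] - 1.0) * c.log_t
                     - beta[c.i] * c.t)
        if (not np.isfinite(log_theta).all()
                or np.abs(log_theta).max() > _LOGTHETA_CAP):
            return -np.inf, np.zeros(self.ndim)
        theta = np.exp(log_theta)
        loglik = float(np.sum(c.sum_y * log_theta - c.n * theta))

        pr = self.priors
        logp = loglik
        logp += float(np.sum(_normal_logpdf(inter, *pr.intercept)))
        logp += float(np.sum(_normal_logpdf(log_alpha, *pr.logalpha)))
        logp += float(np.sum(_normal_logpdf(log_beta, *pr.logbeta)))

        g = c.sum_y - c.n * theta
        grad = np.zeros(self.ndim)
        gi = np.bincount(c.i, weights=g, minlength=self.nG)
        d_alpha = np.bincount(c.i, weights=g * c.log_t, minlength=self.nG)
        d_beta = -np.bincount(c.i, weights=g * c.t, minlength=self.nG)
        grad[self.slices["intercept"]] = (
            gi - (inter - pr.intercept[0]) / pr.intercept[1] ** 2
        )
        grad[self.slices["log_alpha"]] = (
            d_alpha * alpha - (log_alpha - pr.logalpha[0]) / pr.logalpha[1] ** 2
        )
        grad[self.slices["log_beta"]] = (
            d_beta * beta - (log_beta - pr.logbeta[0]) / pr.logbeta[1] ** 2
        )
        return logp, grad

    def logp(self, x: np.ndarray) -> float:
        return self.logp_grad(x)[0]

    def constrain(self, draws: np.ndarray) -> dict:
        return {
            "intercept": draws[..., self.slices["intercept"]],
            "alpha": np.exp(draws[..., self.slices["log_alpha"]]),
            "beta": np.exp(draws[..., self.slices["log_beta"]]),
        }

    def cell_log_theta(self, params: dict) -> np.ndarray:
        c = self.cells
        inter = params["intercept"][..., c.i]
        alpha = params["alpha"][..., c.i]
        beta = params["beta"][..., c.i]
        return inter + (alpha - 1.0) * c.log_t - beta * c.t


def _normal_logpdf(x, mean, sd):
    return -0.5 * ((np.asarray(x) - mean) / sd) ** 2 - np.log(sd) \
        - 0.5 * np.log(2.0 * np.pi)


def build_model(data: CoreBreakDataset, priors: PriorSpec,
                centered: bool = True):
    """Compile the log posterior for a dataset and prior specification."""
    cells = _Cells(data)
    if priors.variant.name == "naive":
        return _NaiveModel(cells, priors)
    return _HierModel(cells, priors, centered=centered)


# --------------------------------------------------------------------------
# posterior container


#: Scalar hyper-parameters reported in convergence diagnostics.
_DIAG_PARAMS = ("psi0", "mu_logalpha", "mu_logbeta", "sigma_logalpha",
                "sigma_logbeta", "rho", "sigma_tau", "sigma_phi")


@dataclass
class PosteriorSamples:
    """MCMC draws of every model parameter plus per-record log likelihoods.

    Arrays in ``posterior`` are indexed (chain, draw, ...); ``cells`` maps
    the trailing axis of the ``phi`` draws to (genotype, block, depth);
    ``log_likelihood`` aligns with ``records`` row order.
    """

    variant: str
    posterior: dict
    log_likelihood: np.ndarray
    cells: pd.DataFrame
    records: pd.DataFrame
    design: DesignConfig | None
    sample_stats: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    @property
    def n_chains(self) -> int:
        return self.log_likelihood.shape[0]

    @property
    def n_draws(self) -> int:
        return self.log_likelihood.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of a parameter with chains flattened into one axis."""
        arr = self.posterior[name]
        return arr.reshape((-1,) + arr.shape[2:])

    def to_inference_data(self):
        """Export to an ``arviz.InferenceData`` (posterior + log_likelihood)."""
        import arviz as az

        post = {}
        for name, arr in self.posterior.items():
            post[name] = arr
        return az.from_dict(
            posterior=post,
            log_likelihood={"y": self.log_likelihood},
        )

    def compute_diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and bulk ESS for the reported scalar parameters."""
        import arviz as az

        rows = []
        names = [n for n in _DIAG_PARAMS if n in self.posterior]
        if not names:  # naive variant: worst case over each vector block
            names = [n for n in ("intercept", "alpha", "beta")
                     if n in self.posterior]
        for name in names:
            arr = self.posterior[name].astype(float)
            if arr.ndim == 2:
                rhat = float(az.rhat(arr))
                ess = float(az.ess(arr))
            else:
                cols = [arr[..., k] for k in range(arr.shape[-1])]
                rhat = max(float(az.rhat(c)) for c in cols)
                ess = min(float(az.ess(c)) for c in cols)
            rows.append({
                "parameter": name,
                "rhat": rhat,
                "ess_bulk": ess,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
            })
        self.diagnostics = pd.DataFrame(
            rows, columns=["parameter", "rhat", "ess_bulk", "mean", "sd"])
        return self.diagnostics

    @property
    def converged(self) -> bool:
        if self.diagnostics is None:
            self.compute_diagnostics()
        d = self.diagnostics
        if len(d) == 0:
            return True
        return bool((d["rhat"] <= 1.01).all() and (d["ess_bulk"] >= 400).all())

    # ----- portable storage (flat array container) -------------------------

    def save(self, path) -> None:
        """Write the posterior store as a single ``.npz`` archive."""
        import json

        payload = {f"posterior/{k}": v for k, v in self.posterior.items()}
        payload["log_likelihood"] = self.log_likelihood
        payload["cells"] = self.cells.to_numpy()
        payload["records"] = self.records.to_numpy()
        meta = {
            "variant": self.variant,
            "design": self.design.to_dict() if self.design else None,
            "sample_stats": {k: np.asarray(v).tolist()
                             for k, v in self.sample_stats.items()},
            "cell_columns": list(self.cells.columns),
            "record_columns": list(self.records.columns),
        }
        payload["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import json

        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            posterior = {
                k.split("/", 1)[1]: z[k] for k in z.files
                if k.startswith("posterior/")
            }
            cells = pd.DataFrame(z["cells"], columns=meta["cell_columns"])
            records = pd.DataFrame(z["records"],
                                   columns=meta["record_columns"])
            design = (DesignConfig.from_mapping(meta["design"])
                      if meta["design"] else None)
            return cls(
                variant=meta["variant"], posterior=posterior,
                log_likelihood=z["log_likelihood"], cells=cells,
                records=records, design=design,
                sample_stats={k: np.asarray(v) for k, v in
                              meta["sample_stats"].items()},
            )


# --------------------------------------------------------------------------
# fitting


def _map_and_mass(model, x0: np.ndarray, optimize: bool = True,
                  hessian: bool = True):
    """Posterior mode by L-BFGS, plus the Hessian diagonal there.

    Returns ``(x_map, inv_mass)`` where ``inv_mass`` approximates the
    posterior variance per coordinate (inverse curvature, clipped to a sane
    range so flat or sloppy directions fall back to unit scale);
    ``inv_mass`` is None when ``hessian`` is false.  With ``optimize``
    false, ``x0`` is taken as the expansion point as-is (used for a point
    mapped in from another parameterization whose own mode is improper).
    """
    from scipy import optimize as sciopt

    def objective(x):
        lp, g = model.logp_grad(x)
        if not np.isfinite(lp):
            return 1e300, np.zeros_like(x)
        return -lp, -g

    if optimize:
        # ftol is relative to |f|, which carries a huge count-data offset,
        # so it must be tiny to let the rule see nat-scale improvements
        res = sciopt.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 3000, "maxcor": 25,
                     "ftol": 1e-13, "gtol": 1e-6},
        )
        x = res.x
    else:
        x = np.asarray(x0, dtype=float)
    if not hessian:
        return x, None
    # Hessian diagonal by central differences of the analytic gradient
    h = np.empty(x.size)
    delta = 1e-4
    for k in range(x.size):
        xp = x.copy(); xp[k] += delta
        xm = x.copy(); xm[k] -= delta
        h[k] = (model.logp_grad(xp)[1][k] - model.logp_grad(xm)[1][k]) \
            / (2.0 * delta)
    curv = np.maximum(-h, 1e-8)
    inv_mass = np.clip(1.0 / curv, 1e-8, 4.0)
    return x, inv_mass


def _hier_init(model: _HierModel) -> np.ndarray:
    """Hierarchical starting point assembled from naive per-genotype fits.

    The naive model's unpooled (intercept, log alpha, log beta) estimates
    seed the effect blocks; their sample moments seed the hyper-parameters
    (with floors so degenerate spreads cannot freeze the scales at zero).
    """
    from .model import default_priors as _dp

    naive = _NaiveModel(model.cells, _dp("naive"))
    xn, _ = _map_and_mass(naive, naive.init_point(), hessian=False)
    inter = xn[naive.slices["intercept"]]
    la = xn[naive.slices["log_alpha"]]
    lb = xn[naive.slices["log_beta"]]

    x = np.zeros(model.ndim)
    sl = model.slices
    x[sl["psi0"]] = inter.mean()
    x[sl["mu_la"]] = la.mean()
    x[sl["mu_lb"]] = lb.mean()
    x[sl["u_la"]] = np.log(max(la.std(), 0.05))
    x[sl["u_lb"]] = np.log(max(lb.std(), 0.05))
    if model.rho_free and la.size >= 3 and la.std() > 0 and lb.std() > 0:
        r = float(np.corrcoef(la, lb)[0, 1])
        x[sl["zr"]] = np.arctanh(np.clip(r, -0.9, 0.9))
    x[sl["u_tau"]] = np.log(max(inter.std(), 0.05))
    x[sl["u_phi"]] = np.log(0.3)
    x[sl["tau"]] = inter          # eta_i = psi0 + tau_i
    x[sl["a"]] = la
    x[sl["b"]] = lb
    return x


def fit(
    data: CoreBreakDataset,
    variant: ModelVariant | str = "model1",
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorSamples:
    """Fit a model variant by adaptive HMC and return posterior draws.

    Emits a warning when any reported split-R-hat exceeds 1.01 or any
    divergent transition occurred during sampling.
    """
    if isinstance(variant, str):
        variant = ModelVariant(variant)
    if priors is None:
        priors = default_priors(variant)
    elif priors.variant.name != variant.name:
        priors = replace(priors, variant=variant)
    if mcmc is None:
        mcmc = McmcConfig()

    model = build_model(data, priors, centered=True)
    init = model.init_point()
    logp0, _ = model.logp_grad(init)
    if not np.isfinite(logp0):
        raise ValueError(
            f"non-finite log posterior at initialization (logp={logp0}); "
            f"init point: {init[:8]}..."
        )

    # Start chains at the posterior mode and seed the mass matrix with the
    # Hessian diagonal there: the Poisson counts make some coordinates
    # orders of magnitude stiffer than others, and warmup alone cannot
    # bridge that scale gap.  For the hierarchical variants the mode search
    # starts from per-genotype naive-model estimates (landing in the basin
    # where the kernel, not the segment noise, carries the depth trend) and
    # runs in the non-centered geometry, whose mode is proper — optimizing
    # the centered density instead would dive into the sigma -> 0 funnel.
    # Two starting points guard against the optimizer's local basins: the
    # naive-based assembly wins when per-genotype kernels are individually
    # well identified, the generic start when several kernel peaks fall
    # beyond the sampled window and unpooled estimates degenerate.
    if isinstance(model, _HierModel):
        ncmodel = _HierModel(model.cells, priors, centered=False)
        starts = [ncmodel.to_noncentered(_hier_init(model)),
                  ncmodel.init_point()]
        modes = [_map_and_mass(ncmodel, x0, hessian=False)[0]
                 for x0 in starts]
        x_nc = max(modes, key=ncmodel.logp)
        init, inv_mass = _map_and_mass(model, ncmodel.to_centered(x_nc),
                                       optimize=False)
    else:
        init, inv_mass = _map_and_mass(model, init)

    cfg = HmcConfig(
        n_chains=mcmc.n_chains, n_warmup=mcmc.n_warmup, n_draws=mcmc.n_draws,
        target_accept=mcmc.target_accept,
    )
    run = sample_hmc(model.logp_grad, init, cfg, seed=mcmc.seed,
                     inv_mass=inv_mass)

    params = model.constrain(run.draws)  # (chain, draw, ...)
    log_theta = model.cell_log_theta(params)  # (chain, draw, n_cells)
    c = model.cells
    loglik = (c.rec_y * log_theta[..., c.rec_cell]
              - np.exp(log_theta[..., c.rec_cell]) - c.rec_lgamma)

    post = PosteriorSamples(
        variant=variant.name,
        posterior=params,
        log_likelihood=loglik,
        cells=c.frame[["genotype", "block", "depth"]].copy(),
        records=data.table.copy(),
        design=data.design,
        sample_stats={
            "accept_rate": run.accept_rate,
            "divergences": run.divergences,
            "step_size": run.step_size,
        },
    )
    post.compute_diagnostics()
    n_div = int(run.divergences.sum())
    bad_rhat = post.diagnostics.loc[post.diagnostics["rhat"] > 1.01]
    if n_div > 0:
        warnings.warn(f"{n_div} divergent transition(s) during sampling",
                      stacklevel=2)
    if len(bad_rhat):
        warnings.warn(
            "split R-hat > 1.01 for: "
            + ", ".join(f"{r.parameter} ({r.rhat:.3f})"
                        for r in bad_rhat.itertuples()),
            stacklevel=2,
        )
    return post


# --------------------------------------------------------------------------
# profiles and credible bands


@dataclass(frozen=True)
class ProfileBand:
    """Depth-wise posterior band of a profile: mean curve plus the lower
    and upper quantiles at the stated credible level."""

    t: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def _psi_draws(post: PosteriorSamples, i: int, j: int) -> np.ndarray:
    """Draws of the plot intercept psi_ij (flattened over chains)."""
    if post.variant == "naive":
        return np.exp(post.stacked("intercept")[:, i - 1])
    psi0 = post.stacked("psi0")
    kappa = post.stacked("kappa")[:, j - 1]
    tau = post.stacked("tau")[:, i - 1]
    return np.exp(psi0 + kappa + tau)


def _check_indices(post: PosteriorSamples, i: int, j: int, level: float):
    n_g = post.posterior["alpha"].shape[-1]
    n_b = (post.posterior["kappa"].shape[-1]
           if "kappa" in post.posterior else int(post.cells["block"].max()))
    if not 1 <= i <= n_g:
        raise ValueError(f"genotype index {i} outside 1..{n_g}")
    if not 1 <= j <= n_b:
        raise ValueError(f"block index {j} outside 1..{n_b}")
    if not 0.0 < level < 1.0:
        raise ValueError("credible level must lie in (0, 1)")


def _band_from_draws(curves: np.ndarray, t: np.ndarray,
                     level: float) -> ProfileBand:
    lo = (1.0 - level) / 2.0
    return ProfileBand(
        t=t,
        mean=curves.mean(axis=0),
        lower=np.quantile(curves, lo, axis=0),        # type-7 interpolation
        upper=np.quantile(curves, 1.0 - lo, axis=0),
        level=level,
    )


def idealized_profile(post: PosteriorSamples, i: int, j: int,
                      level: float = 0.95) -> ProfileBand:
    """Credible band of the denoised profile ``psi_ij * gamma_i(t)``.

    The segment noise phi is excluded, so this is the smooth genotype curve;
    bands for two blocks differ draw-wise by the factor exp(kappa_j' -
    kappa_j).
    """
    _check_indices(post, i, j, level)
    n_d = int(post.cells["depth"].max())
    t = np.arange(1, n_d + 1, dtype=float)
    psi = _psi_draws(post, i, j)
    alpha = post.stacked("alpha")[:, i - 1]
    beta = post.stacked("beta")[:, i - 1]
    curves = psi[:, None] * np.exp(
        (alpha[:, None] - 1.0) * np.log(t) - beta[:, None] * t
    )
    return _band_from_draws(curves, t, level)


def intensity_profile(post: PosteriorSamples, i: int, j: int,
                      level: float = 0.95) -> ProfileBand:
    """Credible band of the plot intensity ``theta_ij(t)`` including phi."""
    _check_indices(post, i, j, level)
    if "phi" not in post.posterior:
        raise ValueError(
            "intensity_profile requires segment effects; the "
            f"{post.variant!r} variant has none")
    n_d = int(post.cells["depth"].max())
    t = np.arange(1, n_d + 1, dtype=float)

    mask = (post.cells["genotype"].to_numpy() == i) \
        & (post.cells["block"].to_numpy() == j)
    depths = post.cells.loc[mask, "depth"].to_numpy()
    if not np.array_equal(np.sort(depths), t.astype(int)):
        raise ValueError(
            f"plot (genotype={i}, block={j}) is missing depth cells; "
            "intensity bands need every depth observed")
    order = np.argsort(depths)
    phi = post.stacked("phi")[:, np.flatnonzero(mask)[order]]

    psi = _psi_draws(post, i, j)
    alpha = post.stacked("alpha")[:, i - 1]
    beta = post.stacked("beta")[:, i - 1]
    curves = psi[:, None] * np.exp(
        (alpha[:, None] - 1.0) * np.log(t) - beta[:, None] * t + phi
    )
    return _band_from_draws(curves, t, level)


@dataclass(frozen=True)
class OverlapResult:
    """Depth-wise closed-interval overlap of two credible bands."""

    t: np.ndarray
    overlaps: np.ndarray  # bool per depth
    fraction: float


def band_overlap(a: ProfileBand, b: ProfileBand) -> OverlapResult:
    """Whether the bands' closed intervals intersect at each depth."""
    if a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
        raise ValueError("bands are on different depth grids")
    overlaps = (a.lower <= b.upper) & (b.lower <= a.upper)
    return OverlapResult(t=a.t, overlaps=overlaps,
                         fraction=float(overlaps.mean()))


# --------------------------------------------------------------------------
# WAIC


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale: ``waic = -2 (lppd - p_waic)``."""

    lppd: float
    p_waic: float
    waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray


def waic_from_matrix(loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws, observations) log-likelihood matrix.

    ``lppd = sum_n log mean_s exp(ll_sn)`` with a stabilized
    log-mean-exp; ``p_waic = sum_n Var_s(ll_sn)`` (unbiased variance).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("log-likelihood matrix must be 2-d (draws, obs)")
    s = loglik.shape[0]
    if s < 2:
        raise ValueError("WAIC needs at least 2 draws")
    m = loglik.max(axis=0)
    pointwise_lppd = m + np.log(np.exp(loglik - m).mean(axis=0))
    pointwise_p = loglik.var(axis=0, ddof=1)
    lppd = float(pointwise_lppd.sum())
    p_waic = float(pointwise_p.sum())
    return WaicResult(lppd=lppd, p_waic=p_waic,
                      waic=-2.0 * (lppd - p_waic),
                      pointwise_lppd=pointwise_lppd, pointwise_p=pointwise_p)


def waic(post: PosteriorSamples) -> WaicResult:
    """WAIC of a fitted model from its per-record log likelihoods."""
    ll = post.log_likelihood
    return waic_from_matrix(ll.reshape(-1, ll.shape[-1]))


# --------------------------------------------------------------------------
# residuals


def quantile_residuals(data: CoreBreakDataset, post: PosteriorSamples,
                       seed: int = 0) -> np.ndarray:
    """Randomized quantile residuals at the posterior-mean intensity.

    For each record, ``u ~ Uniform(F(y-1), F(y))`` with F the Poisson CDF
    at the record's posterior-mean intensity, mapped through the standard
    normal quantile.  Under a well-specified model these are approximately
    iid standard normal.
    """
    df = data.table
    key = post.records[["genotype", "block", "core", "depth"]]
    if not df[["genotype", "block", "core", "depth"]].equals(key):
        raise ValueError("dataset does not match the records the model was "
                         "fitted to")
    y = df["count"].to_numpy()
    # posterior-mean intensity per record, recovered from the fitted draws
    theta = _posterior_mean_theta(post)
    rng = np.random.default_rng(seed)
    f_hi = stats.poisson.cdf(y, theta)
    f_lo = stats.poisson.cdf(y - 1, theta)
    u = f_lo + (f_hi - f_lo) * rng.uniform(size=y.size)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return stats.norm.ppf(u)


def _posterior_mean_theta(post: PosteriorSamples) -> np.ndarray:
    """Posterior-mean intensity per record (cells expanded to records)."""
    cells = post.cells
    lookup = {
        (g, b, d): s
        for s, (g, b, d) in enumerate(cells.itertuples(index=False))
    }
    rec = post.records[["genotype", "block", "depth"]].to_numpy()
    rec_cell = np.array([lookup[tuple(r)] for r in rec])

    if post.variant == "naive":
        i = cells["genotype"].to_numpy() - 1
        inter = post.stacked("intercept")[:, i]
        alpha = post.stacked("alpha")[:, i]
        beta = post.stacked("beta")[:, i]
        t = cells["depth"].to_numpy().astype(float)
        log_theta = inter + (alpha - 1.0) * np.log(t) - beta * t
    else:
        i = cells["genotype"].to_numpy() - 1
        j = cells["block"].to_numpy() - 1
        t = cells["depth"].to_numpy().astype(float)
        psi0 = post.stacked("psi0")[:, None]
        kappa = post.stacked("kappa")[:, j]
        tau = post.stacked("tau")[:, i]
        alpha = post.stacked("alpha")[:, i]
        beta = post.stacked("beta")[:, i]
        phi = post.stacked("phi")
        log_theta = (psi0 + kappa + tau + (alpha - 1.0) * np.log(t)
                     - beta * t + phi)
    return np.exp(log_theta).mean(axis=0)[rec_cell]
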