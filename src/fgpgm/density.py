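"""Joint state/parameter density for GP gradient matching.

For each measured state k the log density combines three Gaussian terms on
the observation grid:

  * a GP prior on the (mean-centred) state values,  N(x_k − μ_k | 0, C_k);
  * the observation model,                          N(y_k | x_k, σ_k² I);
  * gradient matching between the ODE right-hand side evaluated at the
    current states and the GP-implied derivative distribution,
                N( f_k(x_M, x̃_L, θ) | D_k (x_k − μ_k), A_k + γ² I ).

γ is the standard deviation of the model-mismatch term; its square enters
the covariance, consistent with the sd convention used for σ.  The latent
trajectory x̃_L is supplied by the active latent-state strategy (numerical
integration given θ, or sampled values under GP sampling).  For sampled
latent states the same expression applies without the observation term:
gradient matching remains informative even with nothing to fit the state
values to directly.

Parameters carry a flat prior over the admissible domain unless a
``log_prior`` callable is configured; out-of-domain θ gives −inf, which the
sampler treats as a rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .gp import ConditioningError, GPStateModel
from .systems import ODESystem, in_domain

__all__ = [
    "DensityConfig",
    "JointDensity",
    "log_density_observed",
    "log_density_latent",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class DensityConfig:
    #: model-mismatch sd γ linking GP derivatives to the ODE right-hand side
    gamma: float = 0.3
    #: optional log ρ(θ); None means flat over the parameter domain
    log_prior: Callable[[np.ndarray], float] | None = None

    def __post_init__(self):
        if not (self.gamma >= 0.0):
            raise ValueError("gamma must be nonnegative")


class _StateTerm:
    """Precomputed matrices for one sampled state."""

    __slots__ = (
        "index", "mu", "Cinv", "const_prior", "sigma2", "const_obs",
        "Dmat", "Binv", "const_grad", "y",
    )

    def __init__(self, index: int, gp: GPStateModel, gamma: float,
                 y: np.ndarray | None):
        n = gp.times.size
        self.index = index
        self.mu = gp.mean
        Cj = gp.C + gp.jitter * np.eye(n)
        cf = cho_factor(Cj, lower=True)
        self.Cinv = cho_solve(cf, np.eye(n))
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self.const_prior = -0.5 * (logdetC + n * _LOG2PI)

        B = gp.A + gamma**2 * np.eye(n)
        try:
            Lb = cholesky(B, lower=True)
        except np.linalg.LinAlgError:
            raise ConditioningError(
                "A + gamma^2 I is not positive definite; increase gamma or jitter"
            ) from None
        self.Binv = cho_solve((Lb, True), np.eye(n))
        logdetB = 2.0 * float(np.sum(np.log(np.diag(Lb))))
        self.const_grad = -0.5 * (logdetB + n * _LOG2PI)

        self.Dmat = gp.Dmat
        self.y = None
        self.sigma2 = None
        self.const_obs = 0.0
        if y is not None:
            self.y = np.asarray(y, dtype=float)
            self.sigma2 = max(float(gp.noise_sd) ** 2, 1e-300)
            self.const_obs = -0.5 * n * (_LOG2PI + np.log(self.sigma2))

    def logp(self, x: np.ndarray, f: np.ndarray) -> float:
        z = x - self.mu
        val = self.const_prior - 0.5 * float(z @ (self.Cinv @ z))
        if self.y is not None:
            r = self.y - x
            val += self.const_obs - 0.5 * float(r @ r) / self.sigma2
        rg = f - self.Dmat @ z
        val += self.const_grad - 0.5 * float(rg @ (self.Binv @ rg))
        return val


class JointDensity:
    """Evaluator of the gradient-matching log density on a fixed grid.

    Heavy matrix factorizations are done once at construction; a single
    evaluation then costs one vectorized right-hand-side call plus a few
    small matrix–vector products per state, which is what makes the
    componentwise Metropolis sweep affordable.
    """

    def __init__(
        self,
        system: ODESystem,
        times: np.ndarray,
        gp_observed: Mapping[int, GPStateModel],
        y_observed: Mapping[int, np.ndarray],
        cfg: DensityConfig,
        gp_latent: Mapping[int, GPStateModel] | None = None,
    ):
        self.system = system
        self.times = np.asarray(times, dtype=float)
        self.cfg = cfg
        self.observed_indices = tuple(sorted(gp_observed))
        self.latent_sampled_indices = tuple(sorted(gp_latent)) if gp_latent else ()
        self._obs_terms = [
            _StateTerm(k, gp_observed[k], cfg.gamma, y_observed[k])
            for k in self.observed_indices
        ]
        self._lat_terms = [
            _StateTerm(k, gp_latent[k], cfg.gamma, None)
            for k in self.latent_sampled_indices
        ]

    # -- pieces -------------------------------------------------------------
    def _rhs(self, X: np.ndarray, theta: np.ndarray) -> np.ndarray | None:
        with np.errstate(all="ignore"):
            F = self.system.rhs(X, theta, self.times)
        if not np.all(np.isfinite(F)):
            return None
        return F

    def _log_prior(self, theta: np.ndarray) -> float:
        if not in_domain(self.system, theta):
            return -np.inf
        if self.cfg.log_prior is not None:
            return float(self.cfg.log_prior(theta))
        return 0.0

    def observed_logp(self, X: np.ndarray, theta: np.ndarray) -> float:
        """log ρ(x_M, θ | y, φ, σ, γ) up to the evidence constant."""
        lp = self._log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        F = self._rhs(X, theta)
        if F is None:
            return -np.inf
        for term in self._obs_terms:
            lp += term.logp(X[:, term.index], F[:, term.index])
        return lp if np.isfinite(lp) else -np.inf

    def latent_logp(self, X: np.ndarray, theta: np.ndarray) -> float:
        """Latent-state GP prior + gradient matching (no data term)."""
        if not in_domain(self.system, theta):
            return -np.inf
        F = self._rhs(X, theta)
        if F is None:
            return -np.inf
        lp = 0.0
        for term in self._lat_terms:
            lp += term.logp(X[:, term.index], F[:, term.index])
        return lp if np.isfinite(lp) else -np.inf

    def full_logp(self, X: np.ndarray, theta: np.ndarray) -> float:
        """Acceptance density: observed part plus (if sampling) latent part."""
        lp = self.observed_logp(X, theta)
        if self._lat_terms and np.isfinite(lp):
            lp += self.latent_logp(X, theta)
        return lp if np.isfinite(lp) else -np.inf


def _assemble(system, obs_idx, lat_idx, x_M, latent):
    x_M = np.atleast_2d(np.asarray(x_M, dtype=float))
    if x_M.shape[0] == 1 and len(obs_idx) == 1:
        x_M = x_M.reshape(-1, 1)
    n = x_M.shape[0]
    X = np.zeros((n, system.n_states))
    X[:, list(obs_idx)] = x_M
    if lat_idx:
        if latent is None:
            raise ValueError("latent trajectory required for this system")
        latent = np.atleast_2d(np.asarray(latent, dtype=float))
        if latent.shape[0] == 1 and len(lat_idx) == 1:
            latent = latent.reshape(-1, 1)
        X[:, list(lat_idx)] = latent
    return X


def log_density_observed(
    gp: Mapping[int, GPStateModel],
    system: ODESystem,
    x_M: np.ndarray,
    theta: np.ndarray,
    y: np.ndarray,
    cfg: DensityConfig,
    latent: np.ndarray | None = None,
) -> float:
    """Evaluate the observed-state joint log density (scalar).

    ``gp`` maps observed state indices to fitted models; ``x_M`` and ``y``
    have one column per observed index (sorted); ``latent`` carries the
    latent trajectory columns (sorted latent indices) when the system has
    unobserved states.
    """
    obs_idx = tuple(sorted(gp))
    lat_idx = tuple(i for i in range(system.n_states) if i not in obs_idx)
    times = next(iter(gp.values())).times
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and len(obs_idx) == 1:
        y = y.reshape(-1, 1)
    dens = JointDensity(
        system, times, gp, {k: y[:, j] for j, k in enumerate(obs_idx)}, cfg
    )
    X = _assemble(system, obs_idx, lat_idx, x_M, latent)
    return dens.observed_logp(X, np.asarray(theta, dtype=float))


def log_density_latent(
    gp_latent: Mapping[int, GPStateModel],
    system: ODESystem,
    x_M: np.ndarray,
    x_L: np.ndarray,
    theta: np.ndarray,
    cfg: DensityConfig,
) -> float:
    """Latent-state density of the GP-sampling strategy (scalar).

    Contains no observation term: it is the latent GP prior plus latent
    gradient matching, and is structurally independent of the data y.
    """
    lat_idx = tuple(sorted(gp_latent))
    obs_idx = tuple(i for i in range(system.n_states) if i not in lat_idx)
    times = next(iter(gp_latent.values())).times
    dens = JointDensity(
        system, times, {}, {}, cfg, gp_latent=gp_latent
    )
    X = _assemble(system, obs_idx, lat_idx, x_M, x_L)
    return dens.latent_logp(X, np.asarray(theta, dtype=float))
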