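"""Gaussian-process state model and derivative-matching matrices.

Each observed state gets an independent GP prior x_k ~ GP(μ_k, k_φ) with a
constant mean μ_k (the sample mean of its observations).  Because a GP is
closed under differentiation, the state derivatives on the observation grid
are jointly Gaussian with the states; conditioning gives

    ẋ_k | x_k  ~  N( D_k (x_k − μ_k),  A_k ),

with  D = C'(ẋ,x) C(x,x)⁻¹  and  A = C''(ẋ,ẋ) − C' C⁻¹ C'ᵀ,  where C' and
C'' are the analytic kernel derivative cross-covariances ∂k/∂t and
∂²k/∂t∂t'.  These matrices are the core quantities consumed by the
gradient-matching density.

Kernel families: ``rbf``, ``matern52`` (hyperparameters: signal variance,
lengthscale) and ``sigmoid`` (arcsine/MLP-type kernel, hyperparameters
a, b, c), the three used by the benchmark experiments.

Hyperparameters and the noise sd σ are fitted by maximizing the log
marginal likelihood of the (mean-centred) observations,

    log ρ(y | t, φ, σ) = −½ yᵀ(C_φ + σ²I)⁻¹ y − ½ log|C_φ + σ²I| − (n/2) log 2π,

by multi-restart local optimization in log-hyperparameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "Kernel",
    "GPStateModel",
    "GPFitResult",
    "ConditioningError",
    "kernel_eval",
    "kernel_matrices",
    "build_gp_matrices",
    "log_marginal_likelihood",
    "fit_hyperparameters",
    "fit_state_gp",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class ConditioningError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class Kernel:
    """Covariance kernel k_φ(t, t′).

    families and hyperparameters:
      - ``rbf``:      variance v, lengthscale l;  k = v exp(−(t−t′)²/(2l²))
      - ``matern52``: variance v, lengthscale l;  Matérn ν=5/2
      - ``sigmoid``:  a, b, c;  k = a asin((b + c t t′) /
                      sqrt((b + c t² + 1)(b + c t′² + 1)))
    """

    family: str
    params: dict = field(default_factory=dict)

    _REQUIRED = {
        "rbf": ("variance", "lengthscale"),
        "matern52": ("variance", "lengthscale"),
        "sigmoid": ("a", "b", "c"),
    }

    def __post_init__(self):
        if self.family not in self._REQUIRED:
            raise ValueError(
                f"unknown kernel family {self.family!r}; "
                f"known: {sorted(self._REQUIRED)}"
            )
        req = self._REQUIRED[self.family]
        missing = [p for p in req if p not in self.params]
        if missing:
            raise ValueError(f"{self.family} kernel missing hyperparameters {missing}")
        vals = np.array([float(self.params[p]) for p in req])
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise ValueError(
                f"{self.family} hyperparameters must be positive finite, got {self.params}"
            )

    @property
    def hyperparam_names(self) -> tuple[str, ...]:
        return self._REQUIRED[self.family]

    def hyperparam_vector(self) -> np.ndarray:
        return np.array([float(self.params[p]) for p in self.hyperparam_names])


# --- kernel functions and their time derivatives ---------------------------
# Each takes column/row broadcastable arrays T1, T2 and returns the matrix of
# k, ∂k/∂t1 and ∂²k/∂t1∂t2 evaluated elementwise.

def _rbf_all(T1, T2, v, l):
    d = T1 - T2
    e = v * np.exp(-0.5 * (d / l) ** 2)
    k = e
    k1 = -(d / l**2) * e
    k12 = (1.0 / l**2 - (d / l**2) ** 2) * e
    return k, k1, k12


def _matern52_all(T1, T2, v, l):
    d = T1 - T2
    s = np.sqrt(5.0) / l
    ad = np.abs(d)
    e = np.exp(-s * ad)
    k = v * (1.0 + s * ad + (s**2 / 3.0) * d**2) * e
    k1 = -(v * s**2 / 3.0) * d * (1.0 + s * ad) * e
    k12 = (v * s**2 / 3.0) * (1.0 + s * ad - s**2 * d**2) * e
    return k, k1, k12


def _sigmoid_all(T1, T2, a, b, c):
    v1 = b + c * T1**2 + 1.0
    v2 = b + c * T2**2 + 1.0
    u = b + c * T1 * T2
    s = 1.0 / np.sqrt(v1 * v2)
    z = u * s
    z1 = s * (c * T2 - u * c * T1 / v1)
    z2 = s * (c * T1 - u * c * T2 / v2)
    z12 = s * (c - c**2 * T1**2 / v1 - (c * T2 / v2) * (c * T2 - c * u * T1 / v1))
    w = 1.0 - z**2
    w = np.maximum(w, 1e-300)
    k = a * np.arcsin(np.clip(z, -1.0, 1.0))
    k1 = a * z1 / np.sqrt(w)
    k12 = a * (z12 / np.sqrt(w) + z1 * z2 * z / w**1.5)
    return k, k1, k12


def _kernel_all(kernel: Kernel, T1, T2):
    p = kernel.hyperparam_vector()
    if kernel.family == "rbf":
        return _rbf_all(T1, T2, *p)
    if kernel.family == "matern52":
        return _matern52_all(T1, T2, *p)
    return _sigmoid_all(T1, T2, *p)


def kernel_eval(kernel: Kernel, t1: float, t2: float) -> float:
    """Evaluate k_φ(t1, t2); symmetric in its arguments."""
    k, _, _ = _kernel_all(kernel, np.asarray(t1, float), np.asarray(t2, float))
    out = float(k)
    if not np.isfinite(out):
        raise ValueError(f"kernel evaluation not finite at ({t1}, {t2})")
    return out


def kernel_matrices(kernel: Kernel, times: np.ndarray):
    """Return (C, C1, C12): Gram matrix, ∂k/∂t1 and ∂²k/∂t1∂t2 on the grid.

    ``C1[i, j] = ∂k/∂t1 (t_i, t_j)`` is Cov(ẋ(t_i), x(t_j)).
    """
    t = np.asarray(times, dtype=float)
    T1, T2 = t[:, None], t[None, :]
    return _kernel_all(kernel, T1, T2)


@dataclass(frozen=True)
class GPStateModel:
    """Fitted per-state GP with the derivative-matching matrices on a grid."""

    kernel: Kernel
    noise_sd: float
    times: np.ndarray
    mean: float  # constant centring mean μ
    C: np.ndarray  # Gram matrix C_φ (without jitter)
    jitter: float  # diagonal jitter actually added before factorization
    Dmat: np.ndarray  # derivative conditional-mean operator (applied to x − μ)
    A: np.ndarray  # derivative conditional covariance

    def posterior_mean(self, y: np.ndarray, at: np.ndarray | None = None) -> np.ndarray:
        """GP regression posterior mean of the state given observations y."""
        t = self.times
        Ky = self.C + (self.noise_sd**2 + self.jitter) * np.eye(t.size)
        alpha = cho_solve(cho_factor(Ky, lower=True), np.asarray(y, float) - self.mean)
        if at is None:
            return self.mean + self.C @ alpha
        Tq = np.asarray(at, dtype=float)
        Kq, _, _ = _kernel_all(self.kernel, Tq[:, None], t[None, :])
        return self.mean + Kq @ alpha

    def to_text(self) -> str:
        """Plain-text serialization (auditable, resumable)."""
        import hashlib

        h = hashlib.sha256(np.ascontiguousarray(self.times).tobytes()).hexdigest()[:16]
        lines = [f"family: {self.kernel.family}"]
        for name in self.kernel.hyperparam_names:
            lines.append(f"{name}: {self.kernel.params[name]!r}")
        lines += [
            f"noise_sd: {self.noise_sd!r}",
            f"mean: {self.mean!r}",
            f"n_times: {self.times.size}",
            f"grid_sha256: {h}",
        ]
        return "\n".join(lines) + "\n"


def _chol_psd(M: np.ndarray, what: str):
    try:
        return cholesky(M, lower=True)
    except np.linalg.LinAlgError:
        raise ConditioningError(
            f"{what} not positive definite beyond jitter repair "
            f"(condition number ~{np.linalg.cond(M):.3g})"
        ) from None


def build_gp_matrices(
    kernel: Kernel, times: Sequence[float], center: float = 0.0, noise_sd: float = 0.0
) -> GPStateModel:
    """Construct C, D and A for a kernel on a grid of distinct times."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.unique(t).size != t.size:
        raise ValueError("times must be a 1-D grid of distinct points")
    order = np.argsort(t)
    if not np.all(order == np.arange(t.size)):
        raise ValueError("times must be sorted increasing")
    C, C1, C12 = kernel_matrices(kernel, t)
    jitter = 1e-6 * float(np.mean(np.diag(C)))
    L = _chol_psd(C + jitter * np.eye(t.size), "kernel Gram matrix")
    # D = C' C⁻¹ ;  A = C'' − C' C⁻¹ C'ᵀ, computed via triangular solves
    V = solve_triangular(L, C1.T, lower=True)  # L⁻¹ C'ᵀ
    Dmat = solve_triangular(L.T, V, lower=False).T
    A = C12 - V.T @ V
    A = 0.5 * (A + A.T)
    return GPStateModel(
        kernel=kernel,
        noise_sd=float(noise_sd),
        times=t,
        mean=float(center),
        C=C,
        jitter=jitter,
        Dmat=Dmat,
        A=A,
    )


def _lml_centered(kernel, noise_sd, t, yc, jitter=0.0):
    C, _, _ = kernel_matrices(kernel, t)
    K = C + (noise_sd**2 + jitter) * np.eye(t.size)
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        raise ConditioningError("C + σ²I not positive definite") from None
    alpha = solve_triangular(L, yc, lower=True)
    return float(
        -0.5 * alpha @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * t.size * _LOG2PI
    )


def log_marginal_likelihood(
    kernel: Kernel, noise_sd: float, times: Sequence[float], obs: Sequence[float]
) -> float:
    """GP marginal log likelihood of mean-centred observations."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(obs, dtype=float)
    if y.shape != t.shape:
        raise ValueError("obs and times must have equal length")
    return _lml_centered(kernel, noise_sd, t, y - y.mean())


@dataclass(frozen=True)
class GPFitResult:
    kernel: Kernel
    noise_sd: float
    log_marginal: float
    n_restarts: int
    diagnostics: tuple = ()


def _initial_ranges(family: str, times: np.ndarray, y: np.ndarray):
    """Log-uniform sampling ranges for restarts, set by data scales."""
    span = float(times[-1] - times[0])
    sd = float(np.std(y))
    sd = sd if sd > 0 else 1e-3
    if family in ("rbf", "matern52"):
        return {
            "variance": (1e-2 * sd**2, 1e1 * sd**2),
            "lengthscale": (span / 20.0, span),
            "noise_sd": (1e-3 * sd, sd),
        }
    tsq = float(np.mean(times**2)) + 1e-12
    return {
        "a": (1e-2 * sd**2, 1e2 * sd**2),
        "b": (1e-3, 1e1),
        "c": (1e-3 / tsq, 1e1 / tsq),
        "noise_sd": (1e-3 * sd, sd),
    }


def fit_hyperparameters(
    times: Sequence[float],
    obs: Sequence[float],
    family: str = "rbf",
    n_restarts: int = 10,
    seed: int = 0,
) -> GPFitResult:
    """Maximize the marginal likelihood over kernel hyperparameters and σ.

    Runs L-BFGS-B in log-parameter space from ``n_restarts`` seeded
    log-uniform initializations and returns the best local optimum.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(obs, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 observations to fit a GP")
    if np.std(y) == 0:
        warnings.warn(
            "observations are constant; noise sd estimate degenerates to ~0",
            RuntimeWarning,
        )
    names = Kernel._REQUIRED[family]
    ranges = _initial_ranges(family, t, y)
    rng = np.random.default_rng(seed)

    def unpack(logp):
        p = np.exp(logp)
        kern = Kernel(family, dict(zip(names, p[:-1])))
        return kern, float(p[-1])

    yc = y - y.mean()
    # tiny diagonal regularization keeps near-singular smooth kernels
    # optimizable; its effect on the optimum is far below fitting noise
    jit = 1e-10 * (float(np.var(y)) + 1.0)

    def neg_lml(logp):
        try:
            kern, sig = unpack(logp)
            return -_lml_centered(kern, sig, t, yc, jitter=jit)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12

    keys = list(names) + ["noise_sd"]
    bounds = [(np.log(1e-8), np.log(1e8))] * len(keys)
    sd0 = float(np.std(y)) or 1e-3
    span = float(t[-1] - t[0]) or 1.0
    moderate = {
        "variance": sd0**2, "lengthscale": span / 10.0,
        "a": sd0**2, "b": 1.0, "c": 1.0 / (float(np.mean(t**2)) + 1e-12),
        "noise_sd": 0.1 * sd0,
    }
    best = None
    diag = []
    for r in range(n_restarts):
        if r == 0:  # deterministic moderate start, then random restarts
            x0 = np.log([moderate[k] for k in keys])
        else:
            x0 = np.array(
                [
                    rng.uniform(np.log(ranges[k][0]), np.log(ranges[k][1]))
                    for k in keys
                ]
            )
        with np.errstate(all="ignore"):
            res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=bounds)
        val = float(res.fun)
        diag.append((r, val, bool(res.success)))
        if np.isfinite(val) and val < 1e11 and (best is None or val < best[0]):
            best = (val, res.x)
    if best is None:
        raise RuntimeError(f"all {n_restarts} hyperparameter restarts failed: {diag}")
    kern, sig = unpack(best[1])
    return GPFitResult(
        kernel=kern,
        noise_sd=sig,
        log_marginal=-best[0],
        n_restarts=n_restarts,
        diagnostics=tuple(diag),
    )


def fit_state_gp(
    times: Sequence[float],
    obs: Sequence[float],
    family: str = "rbf",
    n_restarts: int = 10,
    seed: int = 0,
) -> GPStateModel:
    """Fit hyperparameters to one observed state and build its D/A matrices."""
    fit = fit_hyperparameters(times, obs, family, n_restarts, seed)
    y = np.asarray(obs, dtype=float)
    return build_gp_matrices(
        fit.kernel, times, center=float(y.mean()), noise_sd=fit.noise_sd
    )
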