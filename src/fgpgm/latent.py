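"""Treatments of unobserved state variables.

Three interchangeable strategies:

``full_integration``
    Integrate the whole ODE system from the (known or configured) initial
    state at each proposed θ and read off the latent components.
``partial_integration``
    Integrate only the latent subsystem by the forward Euler formula,
    treating the measured states as known time-varying coefficients read
    from an interpolant of the observations (by default the fitted GP
    posterior mean, which is already available after Step 1).
``gp_sampling``
    No standalone computation here: the sampler draws the latent state
    values alongside the measured ones, scored by the latent
    gradient-matching density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import _fast
from .systems import (
    IntegrationError,
    ODESystem,
    ObservationScheme,
    SolverConfig,
    integrate,
)

__all__ = [
    "LatentStrategy",
    "latent_full_integration",
    "latent_partial_integration",
]

STRATEGIES = ("full_integration", "partial_integration", "gp_sampling")


@dataclass(frozen=True)
class LatentStrategy:
    kind: str = "full_integration"
    #: interpolation of observed columns under partial_integration
    interpolation: str = "gp_mean"  # or "linear"
    #: forward-Euler step; default = observation span / 1000
    euler_step: float | None = None

    def __post_init__(self):
        if self.kind not in STRATEGIES:
            raise ValueError(f"unknown latent strategy {self.kind!r}; one of {STRATEGIES}")
        if self.interpolation not in ("gp_mean", "linear"):
            raise ValueError("interpolation must be 'gp_mean' or 'linear'")
        if self.euler_step is not None and not self.euler_step > 0:
            raise ValueError("euler_step must be positive")


def latent_full_integration(
    system: ODESystem,
    scheme: ObservationScheme,
    theta: Sequence[float],
    full_initial_state: Sequence[float],
    times: np.ndarray,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """Latent columns of the full-system trajectory at the proposed θ.

    Depends only on θ and the initial values; integration failure
    propagates as :class:`IntegrationError`, which the sampler turns into
    a rejected proposal.
    """
    traj = integrate(system, theta, full_initial_state, times, solver)
    return traj[:, list(scheme.latent_indices)]


def _euler_nodes(times: np.ndarray, step: float):
    """Fine Euler grid containing every observation time.

    Returns (nodes, grid_pos) with grid_pos[i] the node index of times[i].
    """
    times = np.asarray(times, dtype=float)
    gaps = np.diff(times)
    if step > gaps.min() + 1e-12:
        raise ValueError(
            f"euler_step {step} exceeds the smallest observation gap {gaps.min()}"
        )
    nodes = [times[0]]
    grid_pos = [0]
    for t0, t1 in zip(times[:-1], times[1:]):
        m = max(1, int(np.ceil((t1 - t0) / step - 1e-12)))
        seg = t0 + (t1 - t0) * np.arange(1, m + 1) / m
        nodes.extend(seg.tolist())
        grid_pos.append(len(nodes) - 1)
    return np.array(nodes), np.array(grid_pos, dtype=int)


def _euler_latent(
    system: ODESystem,
    obs_idx: Sequence[int],
    lat_idx: Sequence[int],
    theta: np.ndarray,
    obs_at_nodes: np.ndarray,
    nodes: np.ndarray,
    grid_pos: np.ndarray,
    latent_initial: np.ndarray,
) -> np.ndarray:
    """Forward-Euler integration of the latent subsystem on the node grid."""
    if system.fast_id is not None and _fast.HAVE_NUMBA:
        out, ok = _fast.euler_latent_fast(
            system.fast_id,
            np.asarray(theta, dtype=float),
            obs_at_nodes,
            nodes,
            np.asarray(grid_pos, dtype=np.int64),
            np.asarray(latent_initial, dtype=float),
            np.asarray(obs_idx, dtype=np.int64),
            np.asarray(lat_idx, dtype=np.int64),
            system.n_states,
        )
        if not ok:
            raise IntegrationError("forward-Euler blow-up in latent subsystem")
        return out
    lat = np.array(latent_initial, dtype=float)
    x = np.empty(system.n_states)
    out = np.empty((grid_pos.size, lat.size))
    out[0] = lat
    next_out = 1
    lat_list = list(lat_idx)
    obs_list = list(obs_idx)
    rhs = system.rhs
    for i in range(nodes.size - 1):
        x[obs_list] = obs_at_nodes[i]
        x[lat_list] = lat
        f = rhs(x, theta, nodes[i])
        lat = lat + (nodes[i + 1] - nodes[i]) * f[lat_list]
        if not np.all(np.isfinite(lat)):
            raise IntegrationError(
                "forward-Euler blow-up in latent subsystem", last_time=float(nodes[i])
            )
        if next_out < grid_pos.size and i + 1 == grid_pos[next_out]:
            out[next_out] = lat
            next_out += 1
    return out


def latent_partial_integration(
    system: ODESystem,
    scheme: ObservationScheme,
    theta: Sequence[float],
    observed_interpolant: Callable[[np.ndarray], np.ndarray],
    latent_initial: Sequence[float],
    times: np.ndarray,
    step: float | None = None,
) -> np.ndarray:
    """Forward-Euler solution of the latent equations only.

    ``observed_interpolant`` maps a vector of query times to an array of
    observed-state values of shape ``(n_queries, n_observed)``; it must
    cover the full observation span.
    """
    times = np.asarray(times, dtype=float)
    if step is None:
        step = (times[-1] - times[0]) / 1000.0
    nodes, grid_pos = _euler_nodes(times, float(step))
    obs_at_nodes = np.asarray(observed_interpolant(nodes), dtype=float)
    if obs_at_nodes.shape != (nodes.size, len(scheme.observable_indices)):
        raise ValueError(
            "interpolant must return shape (n_queries, n_observed) over the span"
        )
    if not np.all(np.isfinite(obs_at_nodes)):
        raise ValueError("interpolant returned non-finite observed values (coverage gap)")
    theta = np.asarray(theta, dtype=float)
    return _euler_latent(
        system,
        scheme.observable_indices,
        scheme.latent_indices,
        theta,
        obs_at_nodes,
        nodes,
        grid_pos,
        np.asarray(latent_initial, dtype=float),
    )
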