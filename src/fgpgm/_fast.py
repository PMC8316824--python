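"""Compiled fast paths for the sampler's inner loop.

The componentwise Metropolis sweep re-integrates the latent subsystem at
every parameter proposal; going through a Python right-hand side makes
that the dominant cost.  The built-in benchmark systems therefore get
numba-compiled right-hand sides dispatched by a small integer id, plus a
fixed-step classical Runge–Kutta integrator and a forward-Euler latent
integrator that run entirely in compiled code.  Everything falls back to
the generic NumPy implementations when numba is unavailable or the system
is user-defined.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


LV_ID, FHN_ID, PROTEIN_ID, INDIRECT_ID = 0, 1, 2, 3


@njit(cache=False)
def _rhs_fast(sysid, x, th, t, out):
    if sysid == 0:  # Lotka-Volterra
        out[0] = th[0] * x[0] - th[1] * x[0] * x[1]
        out[1] = -th[2] * x[1] + th[3] * x[0] * x[1]
    elif sysid == 1:  # FitzHugh-Nagumo, (a, b, c) parameters
        out[0] = th[2] * (x[0] - x[0] ** 3 / 3.0 + x[1])
        out[1] = -(x[0] - th[0] + th[1] * x[1]) / th[2]
    elif sysid == 2:  # protein transduction
        mm = th[4] * x[4] / (th[5] + x[4])
        out[0] = -th[0] * x[0] - th[1] * x[0] * x[2] + th[2] * x[3]
        out[1] = th[0] * x[0]
        out[2] = -th[1] * x[0] * x[2] + th[2] * x[3] + mm
        out[3] = th[1] * x[0] * x[2] - th[2] * x[3] - th[3] * x[3]
        out[4] = th[3] * x[3] - mm
    else:  # indirect exponential observation, augmented
        out[0] = th[0] * x[1] * np.exp(-th[1] * x[0])
        out[1] = x[0]
        out[2] = th[0] * x[1] * np.exp((1.0 - th[1]) * x[0])


@njit(cache=False)
def rk4_grid(sysid, theta, x0, times, n_steps):
    """Classical RK4 on a grid; returns (trajectory, ok flag)."""
    n = times.shape[0]
    d = x0.shape[0]
    out = np.empty((n, d))
    out[0] = x0
    span = times[-1] - times[0]
    h_target = span / n_steps if span > 0 else 1.0
    x = x0.copy()
    k1 = np.empty(d)
    k2 = np.empty(d)
    k3 = np.empty(d)
    k4 = np.empty(d)
    xt = np.empty(d)
    for i in range(n - 1):
        t0 = times[i]
        t1 = times[i + 1]
        m = int(np.ceil((t1 - t0) / h_target))
        if m < 1:
            m = 1
        h = (t1 - t0) / m
        t = t0
        for _ in range(m):
            _rhs_fast(sysid, x, theta, t, k1)
            for j in range(d):
                xt[j] = x[j] + 0.5 * h * k1[j]
            _rhs_fast(sysid, xt, theta, t + 0.5 * h, k2)
            for j in range(d):
                xt[j] = x[j] + 0.5 * h * k2[j]
            _rhs_fast(sysid, xt, theta, t + 0.5 * h, k3)
            for j in range(d):
                xt[j] = x[j] + h * k3[j]
            _rhs_fast(sysid, xt, theta, t + h, k4)
            for j in range(d):
                x[j] = x[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            t += h
            for j in range(d):
                if not np.isfinite(x[j]):
                    return out, False
        out[i + 1] = x
    return out, True


@njit(cache=False)
def euler_latent_fast(sysid, theta, obs_at_nodes, nodes, grid_pos, lat_init,
                      obs_idx, lat_idx, n_states):
    """Forward Euler of the latent subsystem with observed states as
    known coefficients; returns (latent trajectory on grid, ok flag)."""
    n_lat = lat_idx.shape[0]
    out = np.empty((grid_pos.shape[0], n_lat))
    lat = lat_init.copy()
    out[0] = lat
    x = np.empty(n_states)
    f = np.empty(n_states)
    nxt = 1
    for i in range(nodes.shape[0] - 1):
        for j in range(obs_idx.shape[0]):
            x[obs_idx[j]] = obs_at_nodes[i, j]
        for j in range(n_lat):
            x[lat_idx[j]] = lat[j]
        _rhs_fast(sysid, x, theta, nodes[i], f)
        h = nodes[i + 1] - nodes[i]
        for j in range(n_lat):
            lat[j] = lat[j] + h * f[lat_idx[j]]
            if not np.isfinite(lat[j]):
                return out, False
        if nxt < grid_pos.shape[0] and i + 1 == grid_pos[nxt]:
            out[nxt] = lat
            nxt += 1
    return out, True
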