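"""Synthetic observation datasets: iid Gaussian noise, partial observability,
optional outliers.

The generator reproduces the statistical structure assumed by the inference
model: a noise-free trajectory x(t) observed at discrete times through
Y = X_M + ε with ε ~ N(0, σ²I) on the measured components, latent columns
entirely missing (NaN) apart from an optionally known initial value.
Noise is drawn column-major (state by state, then time) from a single
seeded generator, so masking a state commutes with noise generation and
datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .systems import ODESystem, ObservationScheme, SolverConfig, integrate

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "TimeSeriesDataset",
    "uniform_times",
    "generate_dataset",
    "inject_outliers",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: either an absolute sd or a signal-to-noise
    ratio.  Under SNR the per-state sd is RMS(noise-free column)/snr."""

    mode: str | None = None
    sd: float | None = None
    snr: float | None = None

    def __post_init__(self):
        if self.mode is None:
            object.__setattr__(
                self, "mode", "snr" if self.snr is not None else "absolute_sd"
            )
        if self.mode == "absolute_sd":
            if self.sd is None or self.snr is not None or self.sd < 0:
                raise ValueError("absolute_sd mode needs sd >= 0 and no snr")
        elif self.mode == "snr":
            if self.snr is None or self.sd is not None or self.snr <= 0:
                raise ValueError("snr mode needs snr > 0 and no sd")
        else:
            raise ValueError(f"unknown noise mode {self.mode!r}")

    def per_state_sd(self, truth: np.ndarray) -> np.ndarray:
        """Noise sd for each state column of a noise-free trajectory."""
        n_states = truth.shape[1]
        if self.mode == "absolute_sd":
            return np.full(n_states, float(self.sd))
        rms = np.sqrt(np.mean(truth**2, axis=0))
        if np.any(rms == 0):
            zero = [int(i) for i in np.nonzero(rms == 0)[0]]
            raise ValueError(
                f"snr mode undefined: zero-RMS signal in state column(s) {zero}"
            )
        return rms / float(self.snr)


@dataclass(frozen=True)
class GroundTruth:
    trajectory: np.ndarray  # (N, n_states), noise-free
    theta: np.ndarray
    initial_state: np.ndarray


@dataclass(frozen=True)
class TimeSeriesDataset:
    times: np.ndarray  # (N,) strictly increasing
    values: np.ndarray  # (N, n_states); NaN marks unobserved entries
    state_names: tuple[str, ...]
    scheme: ObservationScheme
    noise: NoiseSpec | None = None
    truth: GroundTruth | None = None
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (t.size, len(self.state_names)):
            raise ValueError("values must have shape (len(times), n_states)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_times(self) -> int:
        return self.times.size

    def observed_values(self) -> np.ndarray:
        """Matrix (N, n_observed) of the measured columns."""
        return self.values[:, list(self.scheme.observable_indices)]

    def latent_initial_values(self) -> dict[int, float]:
        """Known latent initial values, keyed by state index."""
        out = {}
        for k, known in zip(self.scheme.latent_indices, self.scheme.latent_initial_known):
            if known:
                out[k] = float(self.values[0, k])
        return out


def uniform_times(n: int, a: float, b: float) -> np.ndarray:
    """n uniformly spaced observation times on [a, b], endpoints included."""
    if n < 2 or b <= a:
        raise ValueError("need n >= 2 and b > a")
    return np.linspace(a, b, n)


def _resolve_layout(layout) -> np.ndarray:
    if isinstance(layout, tuple) and len(layout) == 3:
        return uniform_times(int(layout[0]), float(layout[1]), float(layout[2]))
    times = np.asarray(layout, dtype=float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("layout must be (n, a, b) or a strictly increasing grid")
    return times


def generate_dataset(
    system: ODESystem,
    params: Sequence[float],
    initial_state: Sequence[float],
    layout,
    noise: NoiseSpec,
    scheme: ObservationScheme,
    seed: int,
    solver: SolverConfig | None = None,
) -> TimeSeriesDataset:
    """Simulate a noisy, partially observed dataset.

    ``layout`` is either ``(n, a, b)`` for n uniform points on [a, b] or an
    explicit strictly increasing time grid.  Latent columns are masked to
    NaN; when the scheme marks a latent initial value as known, the exact
    noise-free initial value is kept at the first time point.
    """
    times = _resolve_layout(layout)
    if scheme.n_states != system.n_states:
        raise ValueError("scheme and system disagree on the number of states")
    truth = integrate(system, params, initial_state, times, solver)
    sds = noise.per_state_sd(truth)

    rng = np.random.default_rng(seed)
    values = truth.copy()
    # fixed draw order: one column of noise per state, in state order
    for k in range(system.n_states):
        values[:, k] += sds[k] * rng.standard_normal(times.size)
    for k, known in zip(scheme.latent_indices, scheme.latent_initial_known):
        values[:, k] = np.nan
        if known:
            values[0, k] = truth[0, k]

    return TimeSeriesDataset(
        times=times,
        values=values,
        state_names=system.state_names,
        scheme=scheme,
        noise=noise,
        truth=GroundTruth(
            trajectory=truth,
            theta=np.asarray(params, dtype=float),
            initial_state=np.asarray(initial_state, dtype=float),
        ),
        seed=seed,
    )


def inject_outliers(
    data: TimeSeriesDataset,
    at_times: Sequence[float],
    magnitude: float | None = None,
    seed: int = 0,
) -> TimeSeriesDataset:
    """Displace the observed entries at the listed grid times by ±magnitude.

    Models abnormally large measurement errors at known times; the sign of
    each displacement is randomized by ``seed``.  Default magnitude is 10×
    the noise sd (the per-state sd under SNR noise).  All other entries are
    returned bit-identical.
    """
    if len(at_times) == 0:
        return data
    idx = []
    for t in at_times:
        hits = np.nonzero(np.isclose(data.times, t, rtol=0, atol=1e-12))[0]
        if hits.size != 1:
            raise ValueError(f"outlier time {t} is not on the observation grid")
        idx.append(int(hits[0]))

    if magnitude is None:
        if data.noise is None or data.truth is None:
            raise ValueError("default magnitude needs noise metadata and truth")
        sds = data.noise.per_state_sd(data.truth.trajectory)
    rng = np.random.default_rng(seed)
    values = data.values.copy()
    for k in data.scheme.observable_indices:
        mag = (10.0 * sds[k]) if magnitude is None else float(magnitude)
        for i in idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[i, k] += sign * mag
    return replace(data, values=values)
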