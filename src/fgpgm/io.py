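"""File formats, run configuration and the end-to-end pipeline.

The single exchange format is CSV with a ``time,<state names>`` header;
empty cells mark unobserved (latent) entries.  A synthetic dataset's
ground truth is written to a sibling ``<stem>.truth.csv`` so a dataset
round-trips losslessly.  Run configuration is a YAML file with blocks for
the system, the data, the GP fit, the density, the sampler, the
refinement and the optional sensitivity analysis.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .data import (
    GroundTruth,
    NoiseSpec,
    TimeSeriesDataset,
    generate_dataset,
    inject_outliers,
)
from .density import DensityConfig
from .gp import GPStateModel, fit_state_gp
from .refine import RefineConfig, refine_least_squares
from .sampler import ChainResult, MCMCConfig, run_mcmc
from .sensitivity import sensitivity_index
from .systems import (
    ODESystem,
    ObservationScheme,
    SolverConfig,
    integrate,
    registry_get,
    system_from_config,
)

__all__ = [
    "FormatError",
    "RunConfig",
    "PipelineResult",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "load_run_config",
    "run_pipeline",
]

log = logging.getLogger("fgpgm")


class FormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _fmt(x: float) -> str:
    return "" if np.isnan(x) else repr(float(x))


def write_timeseries_csv(path, data: TimeSeriesDataset, write_truth: bool = True) -> None:
    """Write a dataset (and its truth sidecar, when present) to CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", *data.state_names])
        for t, row in zip(data.times, data.values):
            w.writerow([repr(float(t)), *[_fmt(v) for v in row]])
    if write_truth and data.truth is not None:
        tpath = path.with_name(path.stem + ".truth.csv")
        with tpath.open("w", newline="") as fh:
            fh.write(f"# theta: {','.join(repr(float(v)) for v in data.truth.theta)}\n")
            fh.write(
                "# initial_state: "
                f"{','.join(repr(float(v)) for v in data.truth.initial_state)}\n"
            )
            if data.noise is not None:
                level = data.noise.sd if data.noise.mode == "absolute_sd" else data.noise.snr
                fh.write(f"# noise: {data.noise.mode},{level}\n")
            if data.seed is not None:
                fh.write(f"# seed: {data.seed}\n")
            w = csv.writer(fh)
            w.writerow(["time", *data.state_names])
            for t, row in zip(data.times, data.truth.trajectory):
                w.writerow([repr(float(t)), *[repr(float(v)) for v in row]])


def _read_rows(path):
    with Path(path).open(newline="") as fh:
        meta = {}
        rows = []
        header = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in cells]
                continue
            if not any(c.strip() for c in cells):
                continue
            rows.append((lineno, cells))
        return meta, header, rows


def read_timeseries_csv(path) -> TimeSeriesDataset:
    """Read a dataset; the observation scheme is inferred from the NaN mask.

    A column that is empty everywhere except (optionally) the first row is
    latent (with a known initial value when the first row is present); any
    other missing entry is a format error.
    """
    path = Path(path)
    _, header, rows = _read_rows(path)
    if header is None or len(header) < 2 or header[0] != "time":
        raise FormatError(f"{path}: header must be 'time,<state names>'")
    state_names = tuple(header[1:])
    times = []
    values = []
    prev_t = None
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise FormatError(
                f"ragged row: {len(cells)} cells, expected {len(header)}", lineno
            )
        try:
            t = float(cells[0])
        except ValueError:
            raise FormatError(f"bad time value {cells[0]!r}", lineno) from None
        if prev_t is not None and t <= prev_t:
            raise FormatError(
                f"times not strictly increasing at t={t!r}", lineno
            )
        prev_t = t
        times.append(t)
        row = []
        for c in cells[1:]:
            c = c.strip()
            row.append(np.nan if c == "" else float(c))
        values.append(row)
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)

    observable, latent_known = [], {}
    for k, name in enumerate(state_names):
        col = values[:, k]
        missing = np.isnan(col)
        if not missing.any():
            observable.append(k)
        elif missing[1:].all():
            latent_known[k] = not missing[0]
        else:
            raise FormatError(
                f"column {name!r} has scattered missing entries; observed "
                "columns must be complete and latent columns empty"
            )
    lat_idx = [k for k in range(len(state_names)) if k not in observable]
    scheme = ObservationScheme(
        n_states=len(state_names),
        observable_indices=tuple(observable),
        latent_initial_known=tuple(latent_known[k] for k in lat_idx),
    )

    truth = None
    seed = None
    noise = None
    tpath = path.with_name(path.stem + ".truth.csv")
    if tpath.exists():
        meta, theader, trows = _read_rows(tpath)
        traj = np.asarray([[float(c) for c in cells[1:]] for _, cells in trows])
        theta = np.asarray([float(v) for v in meta.get("theta", "").split(",")]) \
            if "theta" in meta else np.array([])
        x0 = np.asarray([float(v) for v in meta.get("initial_state", "").split(",")]) \
            if "initial_state" in meta else traj[0]
        truth = GroundTruth(trajectory=traj, theta=theta, initial_state=x0)
        if "seed" in meta:
            seed = int(meta["seed"])
        if "noise" in meta:
            mode, val = meta["noise"].split(",")
            noise = (
                NoiseSpec(mode="absolute_sd", sd=float(val))
                if mode == "absolute_sd"
                else NoiseSpec(mode="snr", snr=float(val))
            )
    return TimeSeriesDataset(
        times=times,
        values=values,
        state_names=state_names,
        scheme=scheme,
        noise=noise,
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    system: dict
    data: dict
    gp: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    refine: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    output_dir: str = "fgpgm_out"

    def resolve_system(self) -> ODESystem:
        if "name" in self.system and "rhs" not in self.system:
            return registry_get(self.system["name"])
        return system_from_config(self.system)


def load_run_config(path) -> RunConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "system" not in raw or "data" not in raw:
        raise FormatError(f"{path}: config must define 'system' and 'data' blocks")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config blocks {sorted(unknown)}")
    return RunConfig(**raw)


def _resolve_dataset(cfg: RunConfig, system: ODESystem) -> TimeSeriesDataset:
    block = cfg.data
    if "path" in block:
        data = read_timeseries_csv(block["path"])
        if data.state_names != system.state_names:
            raise FormatError(
                f"dataset states {data.state_names} do not match "
                f"system states {system.state_names}"
            )
        return data
    synth = block.get("synthesize")
    if synth is None:
        raise FormatError("data block needs 'path' or 'synthesize'")
    for name in synth.get("observed", []):
        system.state_index(name)  # validates before any compute
    scheme = ObservationScheme.from_names(
        system, synth["observed"], synth.get("known_initial", [])
    )
    noise_cfg = synth.get("noise", {"sd": 0.0})
    noise = (
        NoiseSpec(mode="snr", snr=float(noise_cfg["snr"]))
        if "snr" in noise_cfg
        else NoiseSpec(mode="absolute_sd", sd=float(noise_cfg.get("sd", 0.0)))
    )
    layout = synth.get("layout")
    layout = tuple(layout) if isinstance(layout, (list, tuple)) and len(layout) == 3 \
        and not hasattr(layout[0], "__len__") else np.asarray(synth["times"])
    params = synth.get("params", system.default_true_params)
    x0 = synth.get("initial_state", system.default_initial_state)
    data = generate_dataset(
        system, params, x0, layout, noise, scheme, int(synth.get("seed", 0))
    )
    if "outliers" in synth:
        o = synth["outliers"]
        data = inject_outliers(
            data, o["at_times"], o.get("magnitude"), int(o.get("seed", 0))
        )
    return data


@dataclass
class PipelineResult:
    data: TimeSeriesDataset
    gp: Mapping[int, GPStateModel]
    chain: ChainResult
    theta_fgpgm: np.ndarray
    theta_refined: np.ndarray | None
    metrics: dict
    sensitivity: object | None = None


def _dense_grid(times: np.ndarray, n: int = 1000) -> np.ndarray:
    return np.linspace(times[0], times[-1], n)


def _state_errors(system, theta, x0, truth_theta, truth_x0, times, solver=None):
    """Relative L-infinity and L2 reconstruction errors on a dense grid."""
    grid = _dense_grid(times)
    solver = solver or SolverConfig()
    ref = integrate(system, truth_theta, truth_x0, grid, solver)
    rec = integrate(system, theta, x0, grid, solver)
    out = {}
    for k, name in enumerate(system.state_names):
        diff = rec[:, k] - ref[:, k]
        linf = float(np.max(np.abs(diff)) / np.max(np.abs(ref[:, k])))
        l2 = float(
            np.sqrt(np.trapezoid(diff**2, grid) / np.trapezoid(ref[:, k] ** 2, grid))
        )
        out[name] = {"rel_Linf": linf, "rel_L2": l2}
    return out


def _reconstruction_x0(data: TimeSeriesDataset, est_states: np.ndarray,
                       latent_initial: Mapping[int, float]) -> np.ndarray:
    x0 = np.empty(len(data.state_names))
    for k in data.scheme.observable_indices:
        x0[k] = est_states[0, k]
    for k in data.scheme.latent_indices:
        if k in latent_initial:
            x0[k] = latent_initial[k]
        else:
            x0[k] = est_states[0, k]
    return x0


def run_pipeline(cfg: RunConfig, output_dir=None) -> PipelineResult:
    """Fit GPs, run the sampler, refine, and write the result bundle.

    Writes into ``output_dir``: the dataset echo, GP summaries, the chain
    CSV, both θ estimates, reconstructed trajectories at each estimate and
    a metrics JSON with the per-state relative error norms and absolute θ
    errors (when ground truth is available).
    """
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    system = cfg.resolve_system()
    data = _resolve_dataset(cfg, system)
    write_timeseries_csv(out / "dataset.csv", data)

    gp_block = dict(cfg.gp)
    family = gp_block.get("kernel", "rbf")
    n_restarts = int(gp_block.get("n_restarts", 10))
    gp_seed = int(gp_block.get("seed", 0))
    gp = {}
    for k in data.scheme.observable_indices:
        fam = family if isinstance(family, str) else family[data.state_names[k]]
        log.info("fitting %s GP to state %s", fam, data.state_names[k])
        gp[k] = fit_state_gp(
            data.times, data.values[:, k], family=fam,
            n_restarts=n_restarts, seed=gp_seed + k,
        )
    with (out / "gp_summary.txt").open("w") as fh:
        for k, model in sorted(gp.items()):
            fh.write(f"state {data.state_names[k]}\n{model.to_text()}\n")

    dcfg = DensityConfig(**cfg.density)
    mcmc_block = dict(cfg.mcmc)
    mcmc_block.setdefault("latent_initial", None)
    if mcmc_block["latent_initial"] is not None:
        mcmc_block["latent_initial"] = {
            system.state_index(n): float(v)
            for n, v in mcmc_block["latent_initial"].items()
        }
    mcfg = MCMCConfig(**mcmc_block)
    log.info(
        "running MCMC: %d+%d sweeps, gamma=%g, strategy=%s, sigma_s=%s, sigma_p=%s",
        mcfg.n_burnin, mcfg.n_mcmc, dcfg.gamma, mcfg.latent_strategy,
        mcfg.sigma_s, mcfg.sigma_p,
    )
    chain = run_mcmc(data, system, gp, dcfg, mcfg)
    chain.to_csv(out / "chain.csv")
    (out / "chain_summary.txt").write_text(chain.summary(system))

    theta_fgpgm = chain.estimate_theta
    latent_init = dict(data.latent_initial_values())
    if mcfg.latent_initial:
        latent_init.update(mcfg.latent_initial)
    x0_rec = _reconstruction_x0(data, chain.estimate_states, latent_init)

    refine_block = dict(cfg.refine)
    do_refine = refine_block.pop("enabled", True)
    theta_refined = None
    if do_refine:
        # discrepancy-principle stop at the estimated noise floor unless
        # the config pins its own target
        refine_block.setdefault(
            "target_objective",
            float(sum(data.n_times * gp[k].noise_sd**2
                      for k in data.scheme.observable_indices)),
        )
        rcfg = RefineConfig(**refine_block)
        log.info("refining from FGPGM estimate %s", np.round(theta_fgpgm, 4))
        theta_refined = refine_least_squares(
            system, theta_fgpgm, x0_rec, data, rcfg
        ).theta

    estimates = {
        "fgpgm": {n: float(v) for n, v in zip(system.param_names, theta_fgpgm)}
    }
    if theta_refined is not None:
        estimates["fgpgm_opt"] = {
            n: float(v) for n, v in zip(system.param_names, theta_refined)
        }
    (out / "estimates.json").write_text(json.dumps(estimates, indent=2))

    metrics = {"theta": estimates}
    if data.truth is not None and data.truth.theta.size:
        tstar = data.truth.theta
        metrics["theta_error"] = {
            "fgpgm": {
                n: float(abs(v - t))
                for n, v, t in zip(system.param_names, theta_fgpgm, tstar)
            }
        }
        if theta_refined is not None:
            metrics["theta_error"]["fgpgm_opt"] = {
                n: float(abs(v - t))
                for n, v, t in zip(system.param_names, theta_refined, tstar)
            }
        metrics["state_error"] = {
            "fgpgm": _state_errors(
                system, theta_fgpgm, x0_rec, tstar, data.truth.initial_state,
                data.times,
            )
        }
        if theta_refined is not None:
            metrics["state_error"]["fgpgm_opt"] = _state_errors(
                system, theta_refined, x0_rec, tstar, data.truth.initial_state,
                data.times,
            )

    grid = _dense_grid(data.times)
    for label, th in (("fgpgm", theta_fgpgm), ("fgpgm_opt", theta_refined)):
        if th is None:
            continue
        traj = integrate(system, th, x0_rec, grid)
        with (out / f"trajectory_{label}.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", *system.state_names])
            for t, row in zip(grid, traj):
                w.writerow([repr(float(t)), *[repr(float(v)) for v in row]])

    sens = None
    sens_block = dict(cfg.sensitivity)
    if sens_block.pop("enabled", False):
        window = tuple(sens_block.pop("window", (data.times[0], data.times[-1])))
        grid_arg = sens_block.pop("grid", data.times)
        theta_at = np.asarray(
            sens_block.pop("theta", data.truth.theta if data.truth is not None
                           else theta_fgpgm),
            dtype=float,
        )
        x0_at = np.asarray(
            sens_block.pop("initial_state",
                           data.truth.initial_state if data.truth is not None
                           else x0_rec),
            dtype=float,
        )
        sens = sensitivity_index(system, theta_at, x0_at, window, grid_arg,
                                 **sens_block)
        (out / "sensitivity.txt").write_text(sens.to_text())

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return PipelineResult(
        data=data,
        gp=gp,
        chain=chain,
        theta_fgpgm=theta_fgpgm,
        theta_refined=theta_refined,
        metrics=metrics,
        sensitivity=sens,
    )
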