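"""End-to-end computational experiments driven by config files.

Four experiment kinds are provided, mirroring the standard analyses of
the co-evolution model:

``phase_portrait``
    Velocity field of the mean-field dynamics on a regular grid plus the
    corner classification of the orbit started at every grid point.
``timeseries``
    A single stochastic run's cooperator-frequency and link-type-count
    series.
``bias_sweep``
    Final cooperation against the intra-group bias p, with the analytic
    p_c overlay — the "moderate bias maximizes cooperation" experiment.
``initial_sweep``
    Final cooperation against the initial cooperator fraction, with the
    analytic basin boundary x* overlay.

Every experiment is deterministic given (config, seed); results are
written as CSV, the equilibrium analysis as JSON, and a provenance
record (full config + seed + package version) accompanies every output
directory.  Analytic overlays always come from :mod:`intercoop.meanfield`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .abm import SimulationParams, final_cooperation, run as run_abm
from .game import ModelParams, load_params
from .meanfield import (
    classify_equilibria,
    integrate_trajectory,
    interior_fixed_point,
    replicator_field,
)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "phase_portrait",
    "timeseries",
    "bias_sweep",
    "initial_fraction_sweep",
    "run_config",
    "EXPERIMENTS",
]

EXPERIMENTS = ("phase_portrait", "timeseries", "bias_sweep", "initial_sweep")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment.

    ``grid`` is the p-grid for bias sweeps, the x0-grid for initial
    sweeps and the per-axis coordinate vector of the phase-portrait /
    trajectory start grid.  ABM-based experiments additionally use
    ``replicates``, ``horizon``, ``initial_coop_fraction`` and
    ``imitation``.
    """

    experiment: str
    model: ModelParams
    grid: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(11))
    replicates: int = 10
    horizon: int = 10_000_000
    initial_coop_fraction: float = 0.5
    imitation: str = "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid choices: "
                f"{', '.join(EXPERIMENTS)}"
            )
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if any(not (0.0 <= g <= 1.0) for g in self.grid):
            raise ValueError("grid values must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment,
            "grid": [float(g) for g in self.grid],
            "replicates": self.replicates,
            "horizon": self.horizon,
            "initial_coop_fraction": self.initial_coop_fraction,
            "imitation": self.imitation,
            "seed": self.seed,
            "model": {
                "payoff": dataclasses.asdict(self.model.payoff),
                "schedule": {
                    "k_CC": self.model.schedule.k_CC,
                    "k_CD": self.model.schedule.k_CD,
                    "k_DD": self.model.schedule.k_DD,
                },
                "config": dataclasses.asdict(self.model.config),
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        try:
            model = load_params(d.pop("model"))
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"config is missing field {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)} - {"model"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "grid" in d:
            d["grid"] = tuple(float(g) for g in d["grid"])
        return cls(model=model, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(loaded)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point outcome of a sweep with analytic overlays."""

    grid: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    overlays: dict[str, float | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grid": self.grid, "mean": self.mean, "stderr": self.stderr}
        )

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.mean))])


def _sim_params(config: ExperimentConfig, model: ModelParams, x0, seed) -> SimulationParams:
    return SimulationParams(
        model=model,
        initial_coop_fraction=x0,
        horizon=config.horizon,
        seed=seed,
        sample_every=config.horizon,
        stop_when_monomorphic=True,
        imitation=config.imitation,
    )


def phase_portrait(config: ExperimentConfig) -> pd.DataFrame:
    """Velocity field and orbit endpoints on the grid x grid lattice.

    Endpoint classification: "all-C", "all-D", "interior" (not within
    0.05 of a corner after the integration horizon).
    """
    rows = []
    for x1 in config.grid:
        for x2 in config.grid:
            v = replicator_field((x1, x2), config.model)
            traj = integrate_trajectory((x1, x2), config.model, horizon=4000.0)
            term = traj.terminal
            if np.linalg.norm(term - 1.0) < 0.05:
                endpoint = "all-C"
            elif np.linalg.norm(term) < 0.05:
                endpoint = "all-D"
            else:
                endpoint = "interior"
            rows.append(
                {
                    "x1": x1,
                    "x2": x2,
                    "dx1": v[0],
                    "dx2": v[1],
                    "x1_final": term[0],
                    "x2_final": term[1],
                    "endpoint": endpoint,
                }
            )
    return pd.DataFrame(rows)


def timeseries(config: ExperimentConfig) -> pd.DataFrame:
    """One stochastic run, sampled 500 times along the horizon."""
    sp = SimulationParams(
        model=config.model,
        initial_coop_fraction=config.initial_coop_fraction,
        horizon=config.horizon,
        seed=config.seed,
        imitation=config.imitation,
    )
    return run_abm(sp).to_frame()


def bias_sweep(config: ExperimentConfig) -> SweepResult:
    """Final cooperation as a function of the intra-group bias p."""
    means, errs = [], []
    for i, p in enumerate(config.grid):
        model = config.model.with_(p=float(p))
        m, se, _ = final_cooperation(
            _sim_params(
                config, model, config.initial_coop_fraction,
                config.seed + 1000 * i,
            ),
            replicates=config.replicates,
        )
        means.append(m)
        errs.append(se)
    report = classify_equilibria(config.model)
    return SweepResult(
        grid=np.asarray(config.grid),
        mean=np.asarray(means),
        stderr=np.asarray(errs),
        overlays={
            "p_critical": report.p_critical,
            "x_star": report.x_star,
            "bc_critical": report.bc_critical,
        },
    )


def initial_fraction_sweep(config: ExperimentConfig) -> SweepResult:
    """Final cooperation as a function of the initial cooperator fraction."""
    means, errs = [], []
    for i, x0 in enumerate(config.grid):
        m, se, _ = final_cooperation(
            _sim_params(config, config.model, float(x0), config.seed + 1000 * i),
            replicates=config.replicates,
        )
        means.append(m)
        errs.append(se)
    return SweepResult(
        grid=np.asarray(config.grid),
        mean=np.asarray(means),
        stderr=np.asarray(errs),
        overlays={"x_star": interior_fixed_point(config.model)},
    )


def run_config(path: str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the experiment described at ``path``; write artifacts.

    Writes ``result.csv`` (experiment output), ``equilibria.json``
    (mean-field analysis of the configured parameters) and
    ``provenance.json`` (full config, seed and package version) to
    ``outdir`` (default: the config file's directory / its stem).
    Returns the output directory.
    """
    path = Path(path)
    config = ExperimentConfig.from_yaml(path)
    out = Path(outdir) if outdir is not None else path.parent / path.stem
    out.mkdir(parents=True, exist_ok=True)

    if config.experiment == "phase_portrait":
        result = phase_portrait(config)
    elif config.experiment == "timeseries":
        result = timeseries(config)
    elif config.experiment == "bias_sweep":
        sweep = bias_sweep(config)
        result = sweep.to_frame()
    else:  # initial_sweep
        sweep = initial_fraction_sweep(config)
        result = sweep.to_frame()
    result.to_csv(out / "result.csv", index=False)

    classify_equilibria(config.model).to_json(out / "equilibria.json")
    provenance = {
        "config": config.to_dict(),
        "package_version": _pkg_version,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
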