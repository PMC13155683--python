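"""Run configuration: YAML/JSON loading with validation, and result writers.

A run config names one of the three models, exactly one species source
(inline list, the bundled ten-species table, or a random sample from the rate
grids), the model's environment block, solver options, and an optional
experiment block.  Schema violations are reported with the offending field
path and exit the CLI with code 2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import Trajectory
from .equilibrium import EquilibriumSolution
from .experiments import SweepResult
from .fixtures import methods_parameter_grid, table1_fixture
from .kinetics import (
    ChemostatEnvironment,
    MassEnvironment,
    PhenomenologicalSpecies,
    SpeciesKinetics,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "write_trajectory",
    "write_equilibrium",
    "write_sweep",
    "read_trajectory",
]

#: significant digits for CSV floats
CSV_DIGITS = 12


class ConfigError(ValueError):
    """Invalid run configuration; message carries the field path."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    model: str = "mass"  # mass | chemostat | phenomenological
    species_source: str = "table1"  # inline | table1 | grid_sample
    species: list = field(default_factory=list)  # list of dicts
    environment: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    initial_state: Optional[dict] = None
    seed: int = 0

    def build_species(self) -> list:
        """Materialise the species list as kinetics objects."""
        if self.model == "phenomenological":
            return [
                PhenomenologicalSpecies(
                    k=s["k"], p=s["p"], label=str(s.get("label", i + 1))
                )
                for i, s in enumerate(self.species)
            ]
        if self.species_source == "table1":
            flag = bool(self.experiment.get("exponential_species_3", False))
            return table1_fixture(exponential_species_3=flag)
        if self.species_source == "grid_sample":
            n = int(self.experiment.get("n_species", 10))
            rng = np.random.default_rng(self.seed)
            grid = methods_parameter_grid()
            idx = rng.choice(len(grid), size=n, replace=False)
            return [
                SpeciesKinetics(grid[i].a, grid[i].b, grid[i].c, label=str(j + 1))
                for j, i in enumerate(idx)
            ]
        return [
            SpeciesKinetics(
                a=s["a"], b=s["b"], c=s["c"], label=str(s.get("label", i + 1))
            )
            for i, s in enumerate(self.species)
        ]

    def build_environment(self):
        env = self.environment
        try:
            if self.model == "chemostat":
                return ChemostatEnvironment(rho=env["rho"], phi=env["phi"])
            return MassEnvironment(m=env["m"], r=env.get("r", 1.0))
        except KeyError as exc:
            raise ConfigError(f"environment.{exc.args[0]}: required key missing") from exc
        except ValueError as exc:
            raise ConfigError(f"environment: {exc}") from exc


_MODELS = ("mass", "chemostat", "phenomenological")


def _parse(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    model = raw.get("model", "mass")
    if model not in _MODELS:
        raise ConfigError(f"model: must be one of {_MODELS}, got {model!r}")

    sources = [s for s in ("species", "table1", "grid_sample") if s in raw]
    if len(sources) != 1:
        raise ConfigError(
            "species source: exactly one of 'species' (inline), 'table1', "
            f"'grid_sample' must be present, found {sources or 'none'}"
        )
    source_key = sources[0]
    species_source = "inline" if source_key == "species" else source_key
    species = raw.get("species", []) or []
    if species_source == "inline":
        if not isinstance(species, list) or not species:
            raise ConfigError("species: must be a non-empty list")
        for i, s in enumerate(species):
            required = ("k", "p") if model == "phenomenological" else ("a", "b", "c")
            for key in required:
                if key not in s:
                    raise ConfigError(f"species[{i}].{key}: required key missing")

    experiment = dict(raw.get("experiment", {}) or {})
    # table1 / grid_sample options live beside the source key
    if source_key == "table1" and isinstance(raw["table1"], dict):
        experiment.update(raw["table1"])
    if source_key == "grid_sample" and isinstance(raw["grid_sample"], dict):
        experiment.update(raw["grid_sample"])

    env = raw.get("environment", raw.get("chemostat", {}))
    if not isinstance(env, dict):
        raise ConfigError("environment: must be a mapping")

    cfg = RunConfig(
        model=model,
        species_source=species_source,
        species=species,
        environment=env,
        solver=dict(raw.get("solver", {}) or {}),
        experiment=experiment,
        initial_state=raw.get("initial_state"),
        seed=int(raw.get("seed", 0)),
    )
    cfg.build_environment()  # validate eagerly
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return _parse(raw, str(path))


def write_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML; load(write(cfg)) round-trips."""
    raw: dict = {"model": cfg.model, "seed": cfg.seed}
    if cfg.species_source == "inline":
        raw["species"] = cfg.species
    elif cfg.species_source == "table1":
        raw["table1"] = {}
    else:
        raw["grid_sample"] = {}
    raw["environment"] = cfg.environment
    if cfg.solver:
        raw["solver"] = cfg.solver
    if cfg.experiment:
        raw["experiment"] = cfg.experiment
    if cfg.initial_state is not None:
        raw["initial_state"] = cfg.initial_state
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _fmt(x: float) -> str:
    return f"{x:.{CSV_DIGITS}g}"


def _write_csv(df, path, seed: Optional[int]) -> None:
    path = Path(path)
    header = f"# repeco seed={seed}\n" if seed is not None else ""
    body = df.to_csv(index=False, float_format=f"%.{CSV_DIGITS}g")
    path.write_text(header + body)


def write_trajectory(traj: Trajectory, path, seed: Optional[int] = None) -> None:
    """Trajectory CSV: time, x_<label>, y_<label>, mu_<label>, mu_total, phi."""
    _write_csv(traj.to_frame(), path, seed)


def read_trajectory(path):
    """Read back a trajectory CSV as a DataFrame (header comments skipped)."""
    import pandas as pd

    return pd.read_csv(path, comment="#")


def write_equilibrium(sol: EquilibriumSolution, path, seed: Optional[int] = None) -> None:
    """Equilibrium report JSON (numbers unrounded)."""
    report = sol.to_report()
    if seed is not None:
        report["seed"] = seed
    Path(path).write_text(json.dumps(report, indent=2))


def write_sweep(result: SweepResult, path, seed: Optional[int] = None) -> None:
    """Sweep output: <path> gets the per-species tidy CSV, and a sibling
    ``*_summary.csv`` the per-cell summary."""
    path = Path(path)
    _write_csv(result.species, path, seed)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    _write_csv(result.summary, summary_path, seed)
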