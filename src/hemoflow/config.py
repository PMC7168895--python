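"""Study configuration: schema, defaults, (de)serialization.

A study file is YAML (JSON is a YAML subset and therefore also accepted)
with up to four top-level sections::

    solver:  { density_kg_m3, cycle_period_s, n_cycles, report_cycle,
               time_step_s, relative_tolerance, max_nonlinear_iterations,
               mean_flow_rate_ml_s, waveform_amplitude, store_every }
    cohort:  { n_small, n_large, small_height, ... , seed }
    cutoff:  5.0        # small/large height cutoff, mm
    alpha:   0.05       # significance level
    mesh_size: 0.25     # target grid spacing, mm
    log_level: INFO

Missing keys take the study defaults (relative tolerance 0.01, at most 50
nonlinear iterations, 4 cardiac cycles reporting the second, mean inflow
2.6 mL/s, 5 mm cutoff, alpha 0.05); unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .solver import SolverConfig


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    solver: SolverConfig = field(default_factory=SolverConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cutoff: float = 5.0
    alpha: float = 0.05
    mesh_size: float = 0.25
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.cutoff <= 0 or self.mesh_size <= 0:
            raise ValidationError("cutoff and mesh_size must be positive")

    def to_dict(self):
        return {
            "solver": self.solver.to_dict(),
            "cohort": self.cohort.to_dict(),
            "cutoff": self.cutoff,
            "alpha": self.alpha,
            "mesh_size": self.mesh_size,
            "log_level": self.log_level,
        }


_SOLVER_KEYS = set(SolverConfig().to_dict())
_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}
_TOP_KEYS = {"solver", "cohort", "cutoff", "alpha", "mesh_size", "log_level"}


def _check_keys(given, allowed, where):
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(f"unknown {where} key(s): {sorted(unknown)}")


def load_config(path) -> StudyConfig:
    """Load a study configuration, filling defaults; empty file -> defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("study config must be a mapping")
    _check_keys(data, _TOP_KEYS, "top-level")
    solver_d = data.get("solver", {}) or {}
    _check_keys(solver_d, _SOLVER_KEYS, "solver")
    cohort_d = data.get("cohort", {}) or {}
    _check_keys(cohort_d, _COHORT_KEYS, "cohort")
    merged_solver = {**SolverConfig().to_dict(), **solver_d}
    return StudyConfig(
        solver=SolverConfig.from_dict(merged_solver),
        cohort=CohortConfig.from_dict(cohort_d),
        cutoff=data.get("cutoff", 5.0),
        alpha=data.get("alpha", 0.05),
        mesh_size=data.get("mesh_size", 0.25),
        log_level=data.get("log_level", "INFO"),
    )


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def setup_logging(level: str = "INFO", logfile=None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
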