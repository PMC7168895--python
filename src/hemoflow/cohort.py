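"""Synthetic patient cohort: virtual morphologies and rheologies.

The virtual cohort emulates a 21-patient study population: 16 small
(height <= 5 mm) and 5 large (> 5 mm) unruptured saccular aneurysms.
Per-group dome height and ostium diameter are drawn from truncated
normals calibrated to the clinical group means/SDs (small: height
3.4 +/- 0.8 mm, ostium 4.5 +/- 0.8 mm; large: 6.2 +/- 2.4 and
5.9 +/- 1.1 mm); the spherical-cap dome is then solved exactly from that
(height, ostium) pair, so width, ostium area and surface area emerge from
the cap family rather than being sampled.  Each patient receives a Casson
rheology drawn from a physiological band (yield stress 2-20 mPa, Casson
constant 3-5 mPa.s), a synthetic viscometer curve with multiplicative
noise, and a refit of that curve — so the fitting path is exercised
end-to-end and the solver consumes the *refit* parameters, as it would
with measured curves.

Only the morphology is calibration-targeted; all hemodynamic group
differences must emerge from the flow solves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domain import build_2d_domain
from .flowpattern import classify_flow_pattern
from .geometry import ShapeParams, classify_size
from .hemodynamics import summarize
from .rheology import CassonParams, fit_casson, synth_viscosity_curve
from .solver import SolverConfig, SolverFailure, solve_unsteady
from .stats import make_group_tables

logger = logging.getLogger("hemoflow")


class ConfigurationError(ValueError):
    """Cohort constraints cannot be satisfied."""


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and per-group sampling distributions.

    Morphology entries are (mean, SD) in mm; rheology ranges in SI.
    ``seed`` is the master seed; everything downstream is derived from it.
    """

    n_small: int = 16
    n_large: int = 5
    small_height: tuple[float, float] = (3.4, 0.8)
    large_height: tuple[float, float] = (6.2, 2.4)
    small_ostium: tuple[float, float] = (4.5, 0.8)
    large_ostium: tuple[float, float] = (5.9, 1.1)
    parent_diameter: tuple[float, float] = (4.0, 0.4)
    tau_y_range: tuple[float, float] = (0.002, 0.02)
    k_range: tuple[float, float] = (0.003, 0.005)
    viscosity_noise_sd: float = 0.02
    n_curve_points: int = 50
    cutoff: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_small < 0 or self.n_large < 0:
            raise ValueError("group counts must be >= 0")
        for nm in ("small_height", "large_height", "small_ostium", "large_ostium", "parent_diameter"):
            m, sd = getattr(self, nm)
            if sd < 0:
                raise ValueError(f"{nm} SD must be >= 0")
        if self.small_height[0] > self.cutoff + 3.0 * self.small_height[1]:
            raise ConfigurationError("small-group height mean lies above cutoff + 3 SD")
        if self.large_height[0] < self.cutoff - 3.0 * self.large_height[1]:
            raise ConfigurationError("large-group height mean lies below cutoff - 3 SD")

    def to_dict(self):
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d):
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        }
        return cls(**kwargs)


@dataclass(frozen=True)
class VirtualPatient:
    """One synthetic patient: dome shape, rheology curve and Casson fit."""

    patient_id: str
    shape: ShapeParams
    casson_true: CassonParams  # generating parameters
    casson: CassonParams  # refit from the noisy synthetic curve
    inlet_area_mm2: float
    group: str
    curve_seed: int

    def __post_init__(self):
        if self.inlet_area_mm2 <= 0:
            raise ValueError("inlet area must be positive")

    @property
    def height(self) -> float:
        return self.shape.height

    def to_dict(self):
        return {
            "patient_id": self.patient_id,
            "shape": self.shape.to_dict(),
            "casson_true": self.casson_true.to_dict(),
            "casson": self.casson.to_dict(),
            "inlet_area_mm2": self.inlet_area_mm2,
            "group": self.group,
            "curve_seed": self.curve_seed,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            patient_id=d["patient_id"],
            shape=ShapeParams.from_dict(d["shape"]),
            casson_true=CassonParams.from_dict(d["casson_true"]),
            casson=CassonParams.from_dict(d["casson"]),
            inlet_area_mm2=d["inlet_area_mm2"],
            group=d["group"],
            curve_seed=d["curve_seed"],
        )


import functools


@functools.lru_cache(maxsize=256)
def _match_truncnorm(mean, sd, low, high):
    """Underlying (mu, sigma) whose ({low}, {high}]-truncated normal has the
    target mean and SD.

    The published group statistics describe the truncated (size-gated)
    populations, so the generator matches the truncated moments, not the
    untruncated ones.  Where the SD target is unreachable (a hard bound too
    close to the mean caps the attainable spread) only the mean is matched
    at the nominal sigma.
    """
    from scipy import optimize
    from scipy.stats import truncnorm

    def stats(mu, sigma):
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def resid(x):
        m, s = stats(x[0], np.exp(x[1]))
        return [m - mean, s - sd]

    sol = optimize.least_squares(resid, x0=[mean, np.log(sd)], xtol=1e-12, ftol=1e-12)
    if sol.success and np.linalg.norm(sol.fun) < 1e-6 * max(sd, 1.0):
        return float(sol.x[0]), float(np.exp(sol.x[1]))
    # fall back: match the mean only at the nominal sigma
    lo_mu, hi_mu = mean - 20.0 * sd, mean + 20.0 * sd
    f = lambda mu: stats(mu, sd)[0] - mean
    try:
        mu = optimize.brentq(f, lo_mu, hi_mu, xtol=1e-12)
    except ValueError as exc:
        raise ConfigurationError(
            f"cannot calibrate truncated normal to mean {mean}, SD {sd} on ({low}, {high}]"
        ) from exc
    return float(mu), float(sd)


def _truncated_normal(rng, mean, sd, low, high, max_tries=10000, calibrated=True):
    if sd == 0:
        if not (low < mean <= high):
            raise ConfigurationError(f"degenerate draw {mean} outside ({low}, {high}]")
        return mean
    mu, sigma = _match_truncnorm(mean, sd, low, high) if calibrated else (mean, sd)
    for _ in range(max_tries):
        x = rng.normal(mu, sigma)
        if low < x <= high:
            return x
    raise ConfigurationError(
        f"could not draw from N({mu}, {sigma}) within ({low}, {high}] after {max_tries} tries"
    )


def generate_cohort(config: CohortConfig | None = None) -> list[VirtualPatient]:
    """Draw the virtual cohort; a pure function of the configuration."""
    config = config or CohortConfig()
    ss = np.random.SeedSequence(config.seed)
    patients = []
    specs = [("small", config.n_small, config.small_height, config.small_ostium, (0.5, config.cutoff))]
    specs.append(("large", config.n_large, config.large_height, config.large_ostium, (config.cutoff, np.inf)))
    children = ss.spawn(config.n_small + config.n_large)
    k = 0
    for group, n, h_ms, o_ms, (h_lo, h_hi) in specs:
        for idx in range(n):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            height = _truncated_normal(rng, h_ms[0], h_ms[1], h_lo, h_hi)
            ostium = _truncated_normal(rng, o_ms[0], o_ms[1], 1.0, np.inf)
            parent = _truncated_normal(rng, config.parent_diameter[0], config.parent_diameter[1], 1.0, np.inf)
            shape = ShapeParams.from_height_and_ostium(height, ostium, parent_diameter=parent)
            tau_y = rng.uniform(*config.tau_y_range)
            kk = rng.uniform(*config.k_range)
            true = CassonParams(tau_y=tau_y, k=kk)
            curve_seed = int(child.generate_state(1)[0] % (2**31))
            pid = f"{group[0].upper()}{idx + 1:02d}"
            curve = synth_viscosity_curve(
                true,
                n_points=config.n_curve_points,
                noise_sd=config.viscosity_noise_sd,
                seed=curve_seed,
                patient_id=pid,
            )
            refit = fit_casson(curve).params
            patients.append(
                VirtualPatient(
                    patient_id=pid,
                    shape=shape,
                    casson_true=true,
                    casson=refit,
                    inlet_area_mm2=0.25 * np.pi * parent**2,
                    group=classify_size(height, config.cutoff),
                    curve_seed=curve_seed,
                )
            )
    return patients


def save_cohort(patients: list[VirtualPatient], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in patients], fh, indent=1, sort_keys=True)


def load_cohort(path) -> list[VirtualPatient]:
    with open(path) as fh:
        return [VirtualPatient.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# end-to-end study


def patient_curve(patient: VirtualPatient, config: CohortConfig):
    """Regenerate the patient's synthetic viscometer curve (deterministic)."""
    return synth_viscosity_curve(
        patient.casson_true,
        n_points=config.n_curve_points,
        noise_sd=config.viscosity_noise_sd,
        seed=patient.curve_seed,
        patient_id=patient.patient_id,
    )


def run_patient(patient: VirtualPatient, solver_config: SolverConfig, mesh_size: float = 0.25) -> dict:
    """Simulate one patient and return the flat result row."""
    dom = build_2d_domain(patient.shape, mesh_size=mesh_size)
    sol = solve_unsteady(dom, patient.casson, solver_config, inlet_area_mm2=patient.inlet_area_mm2)
    summary = summarize(sol, patient.casson)
    pattern = classify_flow_pattern(sol)
    row = {
        "patient_id": patient.patient_id,
        "size_class": patient.group,
        "height_mm": patient.shape.height,
        "width_mm": patient.shape.width,
        "ostium_diameter_mm": patient.shape.ostium_diameter,
        "ostium_area_mm2": 0.25 * np.pi * patient.shape.ostium_diameter**2,
        "surface_area_mm2": 2.0 * np.pi * patient.shape.dome_radius * patient.shape.height,
        "solver_converged": sol.converged,
    }
    row.update(summary.to_dict())
    row.update(pattern.to_dict())
    return row


def run_study(
    patients: list[VirtualPatient],
    solver_config: SolverConfig | None = None,
    out_dir=None,
    mesh_size: float = 0.25,
    alpha: float = 0.05,
    resume: bool = True,
) -> dict:
    """Run the full pipeline for a cohort: solve, summarize, classify, tabulate.

    Returns ``{"results": DataFrame, "tables": {...}, "failed": [...]}``.
    When ``out_dir`` is given, per-patient JSON rows (resumable), the
    summary CSV, the four tables and a manifest are written there.  A
    patient whose solve fails is flagged and excluded from the tables.
    """
    solver_config = solver_config or SolverConfig()
    out = Path(out_dir) if out_dir is not None else None
    pat_dir = None
    if out is not None:
        pat_dir = out / "patients"
        pat_dir.mkdir(parents=True, exist_ok=True)

    rows, failed = [], []
    for patient in patients:
        cache = pat_dir / f"{patient.patient_id}.json" if pat_dir is not None else None
        if resume and cache is not None and cache.exists():
            with open(cache) as fh:
                rows.append(json.load(fh))
            logger.info("%s: reused cached result", patient.patient_id)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row = run_patient(patient, solver_config, mesh_size=mesh_size)
        except (SolverFailure, ValueError) as exc:
            failed.append({"patient_id": patient.patient_id, "reason": str(exc)})
            logger.warning("%s: solve failed (%s); excluded from tables", patient.patient_id, exc)
            continue
        logger.info(
            "%s: done (converged=%s)", patient.patient_id, row["solver_converged"]
        )
        rows.append(row)
        if cache is not None:
            with open(cache, "w") as fh:
                json.dump(row, fh, indent=1, sort_keys=True)

    results = pd.DataFrame(rows)
    tables = make_group_tables(results, alpha=alpha) if len(results) else {}
    artifacts = {"results": results, "tables": tables, "failed": failed}
    if out is not None:
        write_results(artifacts, out, solver_config=solver_config, mesh_size=mesh_size, alpha=alpha)
    return artifacts


def write_results(artifacts: dict, out_dir, solver_config=None, mesh_size=None, alpha=None, seed=None) -> dict:
    """Write CSV tables, the summary and a checksummed manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    res = artifacts["results"]
    path = out / "summary.csv"
    res.to_csv(path, index=False)
    files.append(path)
    for name, tab in artifacts.get("tables", {}).items():
        path = out / f"{name}.csv"
        tab.to_csv(path, index=False)
        files.append(path)
    if artifacts.get("failed"):
        path = out / "failed_patients.json"
        with open(path, "w") as fh:
            json.dump(artifacts["failed"], fh, indent=1)
        files.append(path)
    for extra in sorted((out / "patients").glob("*.json")) if (out / "patients").exists() else []:
        files.append(extra)

    config_payload = {
        "solver": solver_config.to_dict() if solver_config is not None else None,
        "mesh_size_mm": mesh_size,
        "alpha": alpha,
        "seed": seed,
    }
    config_hash = hashlib.sha256(
        json.dumps(config_payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "config": config_payload,
        "config_hash": config_hash,
        "files": {
            str(f.relative_to(out)): hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
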