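"""Casson shear-thinning blood rheology.

Whole blood behaves as a yield-stress, shear-thinning fluid.  The Casson
constitutive law used throughout this package is

    sqrt(tau) = sqrt(tau_y) + sqrt(k * gamma_dot)      (tau > tau_y)
    gamma_dot = 0                                      (tau <= tau_y)

where ``tau`` is the shear stress [Pa], ``tau_y`` the yield stress [Pa],
``k`` the Casson constant [Pa.s] and ``gamma_dot`` the shear rate [1/s].
Rearranged, the apparent (effective) viscosity is

    mu(gamma_dot) = tau / gamma_dot = (sqrt(tau_y / gamma_dot) + sqrt(k))**2

which diverges as ``gamma_dot -> 0``; evaluation therefore clamps the shear
rate at a regularization floor ``gamma_min`` (default 1 1/s, the lowest
shear rate a scanning capillary-tube viscometer calibrates).  At high shear
``mu -> k``, the Newtonian plateau.

Internal units are SI (Pa, Pa.s, 1/s); measured curves carry viscosity in
centipoise (1 cP = 1e-3 Pa.s) as clinical viscometers report it.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

CP_PER_PA_S = 1000.0  # 1 Pa.s = 1000 cP


def cp_to_pa_s(value_cp):
    """Convert viscosity from centipoise to Pa.s."""
    return np.asarray(value_cp, dtype=float) / CP_PER_PA_S


def pa_s_to_cp(value_pa_s):
    """Convert viscosity from Pa.s to centipoise."""
    return np.asarray(value_pa_s, dtype=float) * CP_PER_PA_S


@dataclass(frozen=True)
class CassonParams:
    """Casson model parameters.

    Attributes
    ----------
    tau_y : float
        Yield stress [Pa], >= 0.
    k : float
        Casson constant [Pa.s], > 0; the high-shear plateau viscosity.
    gamma_min : float
        Regularization floor for the shear rate [1/s] used when
        evaluating the apparent viscosity.
    """

    tau_y: float
    k: float
    gamma_min: float = 1.0

    def __post_init__(self):
        if self.tau_y < 0:
            raise ValueError(f"yield stress must be >= 0, got {self.tau_y}")
        if self.k <= 0:
            raise ValueError(f"Casson constant must be > 0, got {self.k}")
        if self.gamma_min <= 0:
            raise ValueError(f"shear-rate floor must be > 0, got {self.gamma_min}")

    def to_dict(self):
        return {"tau_y_Pa": self.tau_y, "k_Pa_s": self.k, "gamma_min_per_s": self.gamma_min}

    @classmethod
    def from_dict(cls, d):
        return cls(tau_y=d["tau_y_Pa"], k=d["k_Pa_s"], gamma_min=d.get("gamma_min_per_s", 1.0))


@dataclass(frozen=True)
class ViscosityCurve:
    """A measured (or synthetic) whole-blood viscosity profile.

    ``shear_rates`` [1/s] strictly increasing, ``viscosities`` [cP] positive,
    one value per shear rate.
    """

    patient_id: str
    shear_rates: np.ndarray = field(repr=False)
    viscosities: np.ndarray = field(repr=False)

    def __post_init__(self):
        sr = np.asarray(self.shear_rates, dtype=float)
        mu = np.asarray(self.viscosities, dtype=float)
        if sr.ndim != 1 or mu.ndim != 1 or sr.shape != mu.shape:
            raise ValueError("shear_rates and viscosities must be 1-D and equal length")
        if sr.size and not np.all(np.diff(sr) > 0):
            raise ValueError("shear_rates must be strictly increasing")
        if np.any(sr <= 0):
            raise ValueError("shear_rates must be positive")
        if np.any(mu <= 0):
            raise ValueError("viscosities must be positive")
        object.__setattr__(self, "shear_rates", sr)
        object.__setattr__(self, "viscosities", mu)

    def __len__(self):
        return self.shear_rates.size

    def to_csv(self, path_or_buf):
        """Write the curve as CSV with header ``shear_rate_per_s,viscosity_cP``."""
        if hasattr(path_or_buf, "write"):
            self._write(path_or_buf)
        else:
            with open(path_or_buf, "w", newline="") as fh:
                self._write(fh)

    def _write(self, fh):
        w = csv.writer(fh)
        w.writerow(["shear_rate_per_s", "viscosity_cP"])
        for sr, mu in zip(self.shear_rates, self.viscosities):
            w.writerow([repr(float(sr)), repr(float(mu))])

    @classmethod
    def from_csv(cls, path_or_buf, patient_id="unknown"):
        if hasattr(path_or_buf, "read"):
            fh = io.StringIO(path_or_buf.read())
            return cls._read(fh, patient_id)
        with open(path_or_buf, newline="") as fh:
            return cls._read(fh, patient_id)

    @classmethod
    def _read(cls, fh, patient_id):
        r = csv.reader(fh)
        header = next(r)
        if [h.strip() for h in header] != ["shear_rate_per_s", "viscosity_cP"]:
            raise ValueError(f"unexpected viscosity-curve header: {header}")
        rows = [(float(a), float(b)) for a, b in r if a.strip()]
        sr, mu = (np.array(col) for col in zip(*rows))
        return cls(patient_id=patient_id, shear_rates=sr, viscosities=mu)


def effective_viscosity(gamma_dot, params: CassonParams):
    """Apparent Casson viscosity [Pa.s] at shear rate ``gamma_dot`` [1/s].

    Vectorized; the shear rate is clamped below at ``params.gamma_min`` so
    the value stays bounded (the raw law diverges as gamma_dot -> 0).
    Non-increasing in ``gamma_dot`` and tends to ``k`` at high shear.
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    g = np.maximum(g, params.gamma_min)
    mu = (np.sqrt(params.tau_y / g) + np.sqrt(params.k)) ** 2
    return mu if mu.ndim else float(mu)


@dataclass(frozen=True)
class CassonFit:
    """Result of fitting the Casson law to a viscosity curve."""

    params: CassonParams
    residual: float  # RMS residual in sqrt(Pa) of the linearized regression
    clamped: bool  # True if a negative intercept was clamped to tau_y = 0


def fit_casson(curve: ViscosityCurve, gamma_min: float = 1.0) -> CassonFit:
    """Fit (tau_y, k) to a measured viscosity curve.

    The Casson law is exactly linear in transformed variables:
    with ``tau_i = mu_i * gamma_i`` (mu converted from cP to Pa.s),

        sqrt(tau_i) = sqrt(tau_y) + sqrt(k) * sqrt(gamma_i)

    so an ordinary least-squares line of sqrt(tau) on sqrt(gamma) recovers
    ``sqrt(tau_y)`` (intercept) and ``sqrt(k)`` (slope) with no
    initialization.  A negative intercept (super-Newtonian noise) is clamped
    to zero and the slope refit through the origin.  The residual is the RMS
    misfit of sqrt(tau) in sqrt(Pa).
    """
    if len(curve) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(curve)}")
    gamma = curve.shear_rates
    tau = cp_to_pa_s(curve.viscosities) * gamma
    x = np.sqrt(gamma)
    y = np.sqrt(tau)
    slope, intercept = np.polyfit(x, y, 1)
    clamped = False
    if intercept < 0:
        clamped = True
        intercept = 0.0
        slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise ValueError("fit produced non-positive Casson constant; curve is not shear-thinning data")
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    params = CassonParams(tau_y=float(intercept**2), k=float(slope**2), gamma_min=gamma_min)
    return CassonFit(params=params, residual=resid, clamped=clamped)


def casson_tube_flow_rate(radius: float, pressure_gradient: float, params: CassonParams) -> float:
    """Closed-form volumetric flow rate [m^3/s] of Casson flow in a tube.

    For a straight circular tube of radius ``R`` under axial pressure
    gradient ``G`` [Pa/m], wall shear stress is ``tau_w = G R / 2``.  With
    the yield ratio ``xi = tau_y / tau_w`` the classical Casson-Poiseuille
    solution (unyielded plug core of radius ``xi * R``) integrates to

        Q = (pi G R^4 / 8 k) * (1 - 16/7 xi^{1/2} + 4/3 xi - 1/21 xi^4)

    valid for ``xi < 1``; for ``tau_w <= tau_y`` the plug fills the tube and
    ``Q = 0``.  At ``tau_y = 0`` this is exactly Poiseuille flow.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if pressure_gradient < 0:
        raise ValueError("pressure gradient must be non-negative")
    if pressure_gradient == 0.0:
        return 0.0
    tau_w = pressure_gradient * radius / 2.0
    if tau_w <= params.tau_y:
        return 0.0
    xi = params.tau_y / tau_w
    newtonian = np.pi * pressure_gradient * radius**4 / (8.0 * params.k)
    factor = 1.0 - (16.0 / 7.0) * np.sqrt(xi) + (4.0 / 3.0) * xi - (1.0 / 21.0) * xi**4
    return float(newtonian * factor)


def synth_viscosity_curve(
    params: CassonParams,
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int | None = None,
    patient_id: str = "synthetic",
    shear_range: tuple[float, float] = (1.0, 1000.0),
) -> ViscosityCurve:
    """Generate a synthetic viscometer read-out for a known Casson fluid.

    Log-spaced shear rates over ``shear_range`` (the 1-1000 1/s span of a
    scanning capillary-tube viscometer) with multiplicative Gaussian noise
    of relative standard deviation ``noise_sd`` on the viscosity.
    Deterministic given ``seed``.
    """
    if n_points < 3:
        raise ValueError("need n_points >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = shear_range
    gamma = np.logspace(np.log10(lo), np.log10(hi), n_points)
    mu = pa_s_to_cp(effective_viscosity(gamma, params))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mu = mu * (1.0 + noise_sd * rng.standard_normal(n_points))
        if np.any(mu <= 0):  # pathological draw at huge noise_sd
            mu = np.abs(mu) + 1e-12
    return ViscosityCurve(patient_id=patient_id, shear_rates=gamma, viscosities=mu)
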