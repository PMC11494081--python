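"""Time-dependent dielectric screening and the finite-size-particle cation field.

Electron and parent cation are modelled as uniformly charged spheres of radius
``a`` (default 0.099 nm).  The cation potential seen by the electron is the
screened Coulomb form outside the core and a bounded parabola inside,

    U(r) = -k / (eps_r r)                   (r >= a)
    U(r) = -k (3 a^2 - r^2) / (2 eps_r a^3) (r <  a),   k = e^2/(4 pi eps0),

so the potential minimum sits at the origin.  The short-time relative
permittivity eps_r(0) is *calibrated* so that |U(0)| equals the lowest
ionisation energy of liquid water (10.9 eV), which gives eps_r(0) ~ 2.0; the
long-time limit is the static value 78.4, approached with a configurable
relaxation law.  Each cation carries its own dielectric clock, started at the
ionisation event that created it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import K_COULOMB

#: static relative permittivity of water
EPS_STATIC_DEFAULT = 78.4
#: default dielectric relaxation time, fs
RELAXATION_TIME_DEFAULT = 300.0
#: default finite-size particle radius, nm
CORE_RADIUS_DEFAULT = 0.099
#: lowest ionisation energy of liquid water, eV (calibration well depth)
WELL_DEPTH_DEFAULT = 10.9


def calibrate_short_time_eps(radius_a: float, well_depth: float) -> float:
    """Short-time permittivity making the well depth |U(0)| equal well_depth.

    U(0) = -3 k / (2 eps_r a)  =>  eps_r(0) = 3 k / (2 a D).
    """
    if not (radius_a > 0 and well_depth > 0):
        raise ValueError("radius_a and well_depth must be positive")
    return 1.5 * K_COULOMB / (radius_a * well_depth)


@dataclass(frozen=True)
class DielectricResponse:
    """Relaxation law of the relative permittivity around a fresh cation.

    The default law is a single-exponential rise
    eps_r(t) = eps_short + (eps_static - eps_short)(1 - exp(-t/tau)); a frozen
    law (eps_r == eps_short for all t) is available for diagnostics and energy
    bookkeeping tests.
    """

    eps_short: float = calibrate_short_time_eps(CORE_RADIUS_DEFAULT, WELL_DEPTH_DEFAULT)
    eps_static: float = EPS_STATIC_DEFAULT
    relaxation_time: float = RELAXATION_TIME_DEFAULT
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "frozen"):
            raise ValueError(f"unknown relaxation law {self.form!r}")
        if not (self.eps_short > 0 and self.eps_static >= self.eps_short):
            raise ValueError("require 0 < eps_short <= eps_static")
        if not self.relaxation_time > 0:
            raise ValueError("relaxation_time must be positive")

    @classmethod
    def frozen(cls, eps: float | None = None) -> "DielectricResponse":
        e = eps if eps is not None else calibrate_short_time_eps(
            CORE_RADIUS_DEFAULT, WELL_DEPTH_DEFAULT
        )
        return cls(eps_short=e, eps_static=max(e, EPS_STATIC_DEFAULT), form="frozen")


@dataclass(frozen=True)
class CationSite:
    """An immobile parent cation: position, birth time and core radius."""

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    birth_time: float = 0.0
    radius_a: float = CORE_RADIUS_DEFAULT

    def __post_init__(self) -> None:
        if not self.radius_a > 0:
            raise ValueError("radius_a must be positive")


def eps_r(response: DielectricResponse, t_since_birth: np.ndarray | float):
    """Relative permittivity at a time since the parent cation's birth (fs)."""
    t = np.asarray(t_since_birth, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_birth must be >= 0")
    if response.form == "frozen":
        out = np.full_like(t, response.eps_short, dtype=float)
    else:
        out = response.eps_short + (response.eps_static - response.eps_short) * (
            -np.expm1(-t / response.relaxation_time)
        )
    out = np.clip(out, response.eps_short, response.eps_static)
    return float(out) if out.ndim == 0 else out


def potential_energy(
    r: np.ndarray | float,
    t_since_birth: float,
    site: CationSite,
    response: DielectricResponse,
) -> np.ndarray | float:
    """Electron potential energy U(r) = -e Phi(r) in the cation field, eV."""
    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0):
        raise ValueError("r must be >= 0")
    eps = eps_r(response, t_since_birth)
    a = site.radius_a
    with np.errstate(divide="ignore"):
        outside = -K_COULOMB / (eps * np.maximum(rr, 1e-300))
    inside = -K_COULOMB * (3.0 * a**2 - rr**2) / (2.0 * eps * a**3)
    out = np.where(rr >= a, outside, inside)
    return float(out) if out.ndim == 0 else out


def force(
    r_vec: np.ndarray,
    t_since_birth: float,
    site: CationSite,
    response: DielectricResponse,
) -> np.ndarray:
    """Force on the electron from its parent cation, eV/nm (attractive)."""
    rv = np.asarray(r_vec, dtype=float) - np.asarray(site.position, dtype=float)
    if not np.all(np.isfinite(rv)):
        raise ValueError("r_vec must be finite")
    eps = eps_r(response, t_since_birth)
    a = site.radius_a
    r = math.sqrt(float(rv @ rv))
    if r >= a:
        return -K_COULOMB / (eps * r**3) * rv
    return -K_COULOMB / (eps * a**3) * rv


def well_depth(site: CationSite, response: DielectricResponse, t_since_birth: float = 0.0) -> float:
    """|U(0)| at a given cation age; the calibration inverse of eps_r."""
    return -potential_energy(0.0, t_since_birth, site, response)
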