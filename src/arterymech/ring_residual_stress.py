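"""Residual stress in the unloaded arterial ring from the opening angle.

A radially cut arterial ring springs open by the opening angle ``alpha``,
revealing the (nearly) stress-free reference configuration: an open sector
of total central angle 2*(pi - alpha).  The mid-wall radius of the open
sector follows from arc-length preservation of the mid-wall perimeter,

    R_alpha = pi / (pi - alpha) * Rm,        Rm = Ro + to/2  (alpha in rad)

with Ro the luminal radius and to the wall thickness of the closed ex-vivo
ring.  Closing the sector back into a full annulus is a plane incompressible
boundary-value problem: a material circle at open radius R maps to closed
radius r with circumferential stretch

    lambda_theta(R) = pi * r / ((pi - alpha) * R),  lambda_z = 1,
    lambda_r = 1 / (lambda_theta * lambda_z)

and radial equilibrium d(sigma_r)/dr = (sigma_theta - sigma_r)/r with
traction-free inner and outer surfaces.  The single unknown — the closed
inner radius — is found by root-finding on the outer-surface traction; the
Lagrange pressure is eliminated through the stress difference
sigma_theta - sigma_r = lt^2*S_tt - lr^2*S_rr of the GHO law.

The residual circumferential stress is compressive at the inner wall and
tensile at the outer wall; the profile and the three summary scalars
(sigma_theta_in, sigma_theta_out, and their absolute difference) are the
module's outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import brentq

from .gho_constitutive import GHOParams, _diag_pk2

__all__ = [
    "RingGeometry",
    "OpenSector",
    "ResidualStressProfile",
    "open_config_radius",
    "build_open_reference",
    "solve_closure",
    "ClosureSolverError",
]


class ClosureSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class RingGeometry:
    """Closed ex-vivo ring geometry plus measured opening angle.

    ``Ro`` is the luminal (inner) radius in mm by default; set
    ``Ro_is_external=True`` if Ro was measured as the external radius
    (then Rm = Ro - to/2).  ``to`` wall thickness in mm, ``alpha`` opening
    angle in degrees, 0 <= alpha < 180.
    """

    Ro: float
    to: float
    alpha: float
    Ro_is_external: bool = False

    def __post_init__(self) -> None:
        if not (self.Ro > 0 and self.to > 0):
            raise ValueError("Ro and to must be positive")
        if not 0.0 <= self.alpha < 180.0:
            raise ValueError(f"opening angle must be in [0, 180) degrees, got {self.alpha}")
        if self.Ro_is_external and self.Ro - self.to <= 0:
            raise ValueError("external Ro must exceed wall thickness")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha)

    @property
    def r_inner(self) -> float:
        """Closed-configuration inner radius (mm)."""
        return self.Ro - self.to if self.Ro_is_external else self.Ro

    @property
    def r_outer(self) -> float:
        return self.Ro if self.Ro_is_external else self.Ro + self.to

    @property
    def Rm(self) -> float:
        """Closed mid-wall radius, Rm = r_inner + to/2 (mm)."""
        return self.r_inner + 0.5 * self.to


@dataclass(frozen=True)
class OpenSector:
    """Stress-free open reference configuration (all radii in mm)."""

    R_in: float
    R_out: float
    R_mid: float
    half_angle: float  # (pi - alpha), rad; total sector angle is twice this

    @property
    def sector_angle(self) -> float:
        return 2.0 * self.half_angle


@dataclass(frozen=True)
class ResidualStressProfile:
    """Through-wall residual stress in the closed configuration."""

    radii: np.ndarray  # mm, inner -> outer
    sigma_theta: np.ndarray  # kPa
    sigma_r: np.ndarray  # kPa
    sigma_theta_in: float = field(init=False)
    sigma_theta_out: float = field(init=False)
    delta_sigma_theta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "sigma_theta", np.asarray(self.sigma_theta, dtype=float))
        object.__setattr__(self, "sigma_r", np.asarray(self.sigma_r, dtype=float))
        object.__setattr__(self, "sigma_theta_in", float(self.sigma_theta[0]))
        object.__setattr__(self, "sigma_theta_out", float(self.sigma_theta[-1]))
        object.__setattr__(
            self,
            "delta_sigma_theta",
            abs(float(self.sigma_theta[-1]) - float(self.sigma_theta[0])),
        )


def open_config_radius(geometry: RingGeometry) -> float:
    """Open-configuration mid-wall radius R_alpha = pi*Rm/(pi - alpha), mm."""
    return math.pi * geometry.Rm / (math.pi - geometry.alpha_rad)


def build_open_reference(geometry: RingGeometry) -> OpenSector:
    """Open stress-free sector consistent with the closed ring.

    The sector's mid-wall radius honors the arc-length identity and its
    inner/outer radii conserve the cross-sectional area (incompressibility
    at unit axial stretch):

        (pi - alpha) * (R_out^2 - R_in^2) = pi * (r_out^2 - r_in^2)
    """
    beta = math.pi - geometry.alpha_rad  # sector half-angle
    R_mid = open_config_radius(geometry)
    area_closed = math.pi * (geometry.r_outer**2 - geometry.r_inner**2)
    # R_out + R_in = 2*R_mid and beta*(R_out - R_in)*(R_out + R_in) = area
    dR = area_closed / (beta * 2.0 * R_mid)
    R_in = R_mid - 0.5 * dR
    R_out = R_mid + 0.5 * dR
    if R_in <= 0:
        raise ValueError("open sector has non-positive inner radius")
    return OpenSector(R_in=R_in, R_out=R_out, R_mid=R_mid, half_angle=beta)


def _closed_radii(sector: OpenSector, R: np.ndarray, r_in: float) -> np.ndarray:
    """Closed radius r(R) from area conservation at unit axial stretch."""
    k = sector.half_angle / math.pi
    return np.sqrt(r_in**2 + k * (R**2 - sector.R_in**2))


def _stress_difference(
    params: GHOParams, sector: OpenSector, R: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """sigma_theta - sigma_r (kPa) along the wall; pressure cancels."""
    lam_t = math.pi * r / (sector.half_angle * R)
    lam_r = 1.0 / lam_t  # lambda_z = 1
    # diagonal stretches in (circ, long, radial) order
    Sc, _, Sr = _diag_pk2(params, lam_t, np.ones_like(lam_t), lam_r)
    return lam_t**2 * Sc - lam_r**2 * Sr


def solve_closure(
    geometry: RingGeometry,
    params: GHOParams,
    axial_stretch: float = 1.0,
    n_stations: int = 400,
) -> ResidualStressProfile:
    """Solve the plane incompressible ring-closure BVP.

    Returns the residual stress profile on ``n_stations`` radial stations
    (inner to outer) in the closed configuration.  ``axial_stretch`` other
    than 1 is not supported by the plane formulation and raises.
    """
    if axial_stretch != 1.0:
        raise NotImplementedError("only unit axial stretch is supported")
    if n_stations < 50:
        raise ValueError("need at least 50 radial stations")
    sector = build_open_reference(geometry)
    R = np.linspace(sector.R_in, sector.R_out, n_stations)

    if geometry.alpha == 0.0:
        zeros = np.zeros(n_stations)
        return ResidualStressProfile(radii=R.copy(), sigma_theta=zeros, sigma_r=zeros.copy())

    def outer_traction(r_in: float) -> float:
        r = _closed_radii(sector, R, r_in)
        dq = _stress_difference(params, sector, R, r)
        return float(trapezoid(dq / r, r))

    # bracket the closed inner radius around the zero-hoop-strain guess
    r0 = sector.half_angle / math.pi * sector.R_in
    lo, hi = 0.2 * r0, 3.0 * r0
    f_lo, f_hi = outer_traction(lo), outer_traction(hi)
    expand = 0
    while f_lo * f_hi > 0 and expand < 30:
        lo *= 0.7
        hi *= 1.3
        f_lo, f_hi = outer_traction(lo), outer_traction(hi)
        expand += 1
    if f_lo * f_hi > 0:
        raise ClosureSolverError(
            f"could not bracket closed inner radius in [{lo:.4g}, {hi:.4g}] mm"
        )
    r_in = brentq(outer_traction, lo, hi, xtol=1e-13, rtol=1e-14)

    r = _closed_radii(sector, R, r_in)
    dq = _stress_difference(params, sector, R, r)
    sigma_r = cumulative_trapezoid(dq / r, r, initial=0.0)
    sigma_theta = sigma_r + dq
    return ResidualStressProfile(radii=r, sigma_theta=sigma_theta, sigma_r=sigma_r)
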