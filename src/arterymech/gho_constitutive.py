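"""Gasser-Holzapfel-Ogden (GHO) hyperelastic model for arterial tissue.

The artery wall is modelled as an incompressible isotropic ground matrix
(elastin, shear modulus ``mu``) reinforced by two symmetric families of
collagen fibers lying in the circumferential-longitudinal plane.  Each family
makes a mean angle ``gamma`` with the *longitudinal* duct axis and is
dispersed with parameter ``kappa`` (0 = perfectly aligned, 1/3 = isotropic).

Strain energy density (kPa), with ``C`` the right Cauchy-Green tensor::

    W(C) = mu/2 (I1 - 3)
         + k1/(2 k2) * sum_{i=4,6} [ exp(k2 * E_i^2) - 1 ]

    E_i = kappa*I1 + (1 - 3*kappa)*I_i - 1
    I1  = tr C,   I4 = a1.C.a1,   I6 = a2.C.a2

Component order of all vectors/tensors is fixed as
(circumferential, longitudinal, radial), so the fiber directions are
literally ``a1 = (sin g, cos g, 0)`` and ``a2 = (-sin g, cos g, 0)``.
Angles are degrees at every public interface, radians internally.

Incompressibility (det F = 1) is enforced through a Lagrange-multiplier
pressure ``p``; the Cauchy stress is ``sigma = F S F^T - p I`` with ``S``
the (p-free part of the) second Piola-Kirchhoff stress, obtained as the
exact derivative ``S = 2 dW/dC``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Direction",
    "GHOParams",
    "KinematicState",
    "UniaxialState",
    "StressStretchCurve",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_response",
    "forward_curves",
]

#: index of each physical axis in the fixed component order
CIRC, LONG, RADIAL = 0, 1, 2

_KINEMATIC_TOL = 1e-10


class Direction(str, Enum):
    """Loading direction of a uniaxial tensile specimen."""

    CIRCUMFERENTIAL = "circumferential"
    LONGITUDINAL = "longitudinal"


@dataclass(frozen=True)
class GHOParams:
    """The five GHO material constants.

    mu, k1 in kPa; k2, kappa dimensionless; gamma in degrees measured from
    the longitudinal duct axis.  ``fiber_tension_only`` optionally zeroes a
    fiber family's stress contribution when its pseudo-invariant is below 1
    (fiber under compression) — the original GHO convention.  The default
    keeps the fiber terms active everywhere, i.e. the constitutive law
    exactly as written.
    """

    mu: float
    k1: float
    k2: float
    kappa: float
    gamma: float
    fiber_tension_only: bool = False

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError(f"kappa must be in [0, 1/3], got {self.kappa}")
        if not 0.0 <= self.gamma <= 90.0:
            raise ValueError(f"gamma must be in [0, 90] degrees, got {self.gamma}")

    @property
    def gamma_rad(self) -> float:
        return math.radians(self.gamma)

    def fiber_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit fiber directions a1, a2 in (circ, long, radial) components."""
        s, c = math.sin(self.gamma_rad), math.cos(self.gamma_rad)
        return np.array([s, c, 0.0]), np.array([-s, c, 0.0])

    def to_dict(self) -> dict:
        return {
            "mu_kPa": self.mu,
            "k1_kPa": self.k1,
            "k2": self.k2,
            "kappa": self.kappa,
            "gamma_deg": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GHOParams":
        return cls(
            mu=float(d["mu_kPa"]),
            k1=float(d["k1_kPa"]),
            k2=float(d["k2"]),
            kappa=float(d["kappa"]),
            gamma=float(d["gamma_deg"]),
            fiber_tension_only=bool(d.get("fiber_tension_only", False)),
        )


@dataclass(frozen=True)
class KinematicState:
    """Deformation state: F, C = F^T F, J = det F, pressure p, invariants."""

    F: np.ndarray
    p: float = 0.0

    C: np.ndarray = field(init=False)
    J: float = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        J = float(np.linalg.det(F))
        if J <= 0:
            raise ValueError(f"det F must be positive, got {J}")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "C", F.T @ F)
        object.__setattr__(self, "J", J)

    @property
    def is_incompressible(self) -> bool:
        return abs(self.J - 1.0) <= _KINEMATIC_TOL

    def invariants(self, params: GHOParams) -> tuple[float, float, float]:
        """(I1, I4, I6) of this state for the given fiber geometry."""
        a1, a2 = params.fiber_vectors()
        return (
            float(np.trace(self.C)),
            float(a1 @ self.C @ a1),
            float(a2 @ self.C @ a2),
        )


@dataclass(frozen=True)
class UniaxialState:
    """Equilibrium state of an incompressible uniaxial tensile specimen.

    ``lambda1`` is the applied stretch along the loading axis, ``lambda2``
    the transverse in-plane (width) stretch, ``lambda3`` the radial
    (thickness) stretch; the lateral Cauchy stresses vanish and ``sigma1``
    is the axial Cauchy stress in kPa.
    """

    direction: Direction
    lambda1: float
    lambda2: float
    lambda3: float
    sigma1: float
    p: float

    def __post_init__(self) -> None:
        if abs(self.lambda1 * self.lambda2 * self.lambda3 - 1.0) > _KINEMATIC_TOL:
            raise ValueError("uniaxial state violates incompressibility")


@dataclass(frozen=True)
class StressStretchCurve:
    """Ordered Cauchy stress (kPa) vs stretch samples of one tensile test."""

    stretch: np.ndarray
    stress: np.ndarray
    direction: Direction | None = None
    lambda2: np.ndarray | None = None
    lambda3: np.ndarray | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretch and stress must be equal-length 1-D arrays")
        if lam.size and np.any(np.diff(lam) < 0):
            raise ValueError("stretch must be non-decreasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "stress", sig)

    def __len__(self) -> int:
        return self.stretch.size


# ----------------------------------------------------------------------------
# energy and stress
# ----------------------------------------------------------------------------

def _check_C(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise ValueError("C must be 3x3")
    if not np.allclose(C, C.T, rtol=0, atol=1e-9 * max(1.0, float(np.abs(C).max()))):
        raise ValueError("C must be symmetric")
    if np.any(np.linalg.eigvalsh(C) <= 0):
        raise ValueError("C must be positive-definite")
    return 0.5 * (C + C.T)


def strain_energy(params: GHOParams, C: np.ndarray) -> float:
    """GHO strain-energy density W(C) in kPa.

    Both fiber families are summed.  Raises ``ValueError`` for a
    non-symmetric or non-positive-definite C.
    """
    C = _check_C(C)
    I1 = float(np.trace(C))
    a1, a2 = params.fiber_vectors()
    W = 0.5 * params.mu * (I1 - 3.0)
    for a in (a1, a2):
        Ii = float(a @ C @ a)
        if params.fiber_tension_only and Ii < 1.0:
            continue
        E = params.kappa * I1 + (1.0 - 3.0 * params.kappa) * Ii - 1.0
        W += params.k1 / (2.0 * params.k2) * math.expm1(params.k2 * E * E)
    return W


def _pk2_isochoric(params: GHOParams, C: np.ndarray) -> np.ndarray:
    """p-free part of the second Piola-Kirchhoff stress, S = 2 dW/dC."""
    I1 = float(np.trace(C))
    a1, a2 = params.fiber_vectors()
    S = params.mu * np.eye(3)
    for a in (a1, a2):
        Ii = float(a @ C @ a)
        if params.fiber_tension_only and Ii < 1.0:
            continue
        E = params.kappa * I1 + (1.0 - 3.0 * params.kappa) * Ii - 1.0
        psi = 2.0 * params.k1 * E * math.exp(params.k2 * E * E)
        S += psi * (params.kappa * np.eye(3) + (1.0 - 3.0 * params.kappa) * np.outer(a, a))
    return S


def cauchy_stress(params: GHOParams, F: np.ndarray, p: float) -> np.ndarray:
    """Cauchy stress sigma = J^-1 F S F^T - p I (kPa), S = 2 dW/dC.

    ``p`` is the Lagrange-multiplier pressure.  Raises ``ValueError`` on a
    singular F.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("F must be 3x3")
    J = float(np.linalg.det(F))
    if abs(J) < 1e-14:
        raise ValueError("F is singular")
    if J <= 0:
        raise ValueError("det F must be positive")
    C = F.T @ F
    S = _pk2_isochoric(params, C)
    sigma = (F @ S @ F.T) / J - p * np.eye(3)
    return 0.5 * (sigma + sigma.T)


# ----------------------------------------------------------------------------
# semi-analytic uniaxial solution
# ----------------------------------------------------------------------------

def _axis_stretches(direction: Direction, lam1, lam2, lam3):
    """Map (loading, transverse, thickness) stretches onto the fixed
    (circ, long, radial) axes for the given loading direction."""
    if direction == Direction.CIRCUMFERENTIAL:
        return lam1, lam2, lam3
    return lam2, lam1, lam3


#: cap on the log of the fiber stress factor; keeps extreme trial states
#: finite (sign-correct) instead of overflowing to NaN during root bracketing
_LOG_PSI_MAX = 700.0


def _fiber_psi(params: GHOParams, I1, I4):
    """Per-family fiber stress factor 2*k1*E*exp(k2*E^2), overflow-safe."""
    E = params.kappa * I1 + (1.0 - 3.0 * params.kappa) * I4 - 1.0
    absE = np.abs(E)
    with np.errstate(divide="ignore"):
        log_psi = np.where(
            absE > 0,
            np.log(2.0 * params.k1 * np.maximum(absE, 1e-300)) + params.k2 * E * E,
            -np.inf,
        )
    psi = np.sign(E) * np.exp(np.minimum(log_psi, _LOG_PSI_MAX))
    if params.k1 == 0.0:
        psi = np.zeros_like(psi)
    if params.fiber_tension_only:
        psi = np.where(I4 < 1.0, 0.0, psi)
    return psi


def _diag_pk2(params: GHOParams, lam_c, lam_l, lam_r):
    """Diagonal of the p-free S for a diagonal C = diag(lc^2, ll^2, lr^2).

    Vectorized over numpy arrays.  For diagonal C the two fiber families
    share the same pseudo-invariant, so their contributions coincide.
    """
    g = params.gamma_rad
    s2, c2 = math.sin(g) ** 2, math.cos(g) ** 2
    Cc, Cl, Cr = lam_c**2, lam_l**2, lam_r**2
    I1 = Cc + Cl + Cr
    I4 = s2 * Cc + c2 * Cl  # = I6 for diagonal C
    psi = _fiber_psi(params, I1, I4)
    kap, one3k = params.kappa, 1.0 - 3.0 * params.kappa
    # two identical families -> factor 2
    Sc = params.mu + 2.0 * psi * (kap + one3k * s2)
    Sl = params.mu + 2.0 * psi * (kap + one3k * c2)
    Sr = params.mu + 2.0 * psi * kap
    return Sc, Sl, Sr


def _lateral_gap(params: GHOParams, direction: Direction, lam1, lam2):
    """sigma2 - sigma3 as a function of the transverse stretch lam2.

    With diagonal kinematics sigma_i = lam_i^2 S_ii - p, so the pressure
    cancels in the difference; the uniaxial equilibrium root satisfies
    sigma2 = sigma3 = 0 once p is set from sigma3 = 0.
    """
    lam3 = 1.0 / (lam1 * lam2)
    g = params.gamma_rad
    s2, c2 = math.sin(g) ** 2, math.cos(g) ** 2
    lc, ll, lr = _axis_stretches(direction, lam1, lam2, lam3)
    I1 = lc**2 + ll**2 + lr**2
    I4 = s2 * lc**2 + c2 * ll**2
    psi = _fiber_psi(params, I1, I4)
    kap, one3k = params.kappa, 1.0 - 3.0 * params.kappa
    # transverse in-plane fiber weight for the given loading direction
    a_t = kap + one3k * (c2 if direction == Direction.CIRCUMFERENTIAL else s2)
    # psi factored out so the sign survives even when psi saturates
    with np.errstate(over="ignore"):
        return params.mu * (lam2**2 - lam3**2) + 2.0 * psi * (lam2**2 * a_t - lam3**2 * kap)


class ConvergenceError(RuntimeError):
    """Raised when the lateral-stress root of the uniaxial problem is lost."""


def _solve_lambda2(params: GHOParams, direction: Direction, lam1: np.ndarray) -> np.ndarray:
    """Vectorized solve of sigma2(lam2) = sigma3(lam2) = 0 for each lam1.

    Bisection on log(lam2) over (0, 1.5]; the gap function is -inf-like as
    lam2 -> 0 (thickness blow-up) and positive once the transverse term
    dominates, so a sign change is bracketed and bisection is safe.
    """
    lam1 = np.asarray(lam1, dtype=float)
    lo = np.full(lam1.shape, math.log(1e-3))
    hi = np.full(lam1.shape, math.log(1.5))
    g_lo = _lateral_gap(params, direction, lam1, np.exp(lo))
    g_hi = _lateral_gap(params, direction, lam1, np.exp(hi))
    bad = (g_lo > 0) | (g_hi < 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ConvergenceError(
            "no transverse-stretch root in (0.001, 1.5] for "
            f"lambda1={lam1.flat[i]:.4g}, direction={direction.value}, params={params}"
        )
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        g_mid = _lateral_gap(params, direction, lam1, np.exp(mid))
        neg = g_mid < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return np.exp(0.5 * (lo + hi))


def uniaxial_sigma1(
    params: GHOParams, direction: Direction, lam1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized incompressible uniaxial response.

    Returns ``(sigma1, lambda2, lambda3, p)`` arrays for the applied
    stretches ``lam1`` with both lateral Cauchy stresses zero.
    """
    lam1 = np.atleast_1d(np.asarray(lam1, dtype=float))
    lam2 = _solve_lambda2(params, direction, lam1)
    lam3 = 1.0 / (lam1 * lam2)
    lc, ll, lr = _axis_stretches(direction, lam1, lam2, lam3)
    Sc, Sl, Sr = _diag_pk2(params, lc, ll, lr)
    p = lam3**2 * Sr
    S1 = Sc if direction == Direction.CIRCUMFERENTIAL else Sl
    sigma1 = lam1**2 * S1 - p
    return sigma1, lam2, lam3, p


def uniaxial_response(
    params: GHOParams, direction: Direction | str, lambda1: float
) -> UniaxialState:
    """Solve the incompressible uniaxial tensile state at stretch lambda1.

    Finds the transverse stretch lambda2 and pressure p such that the two
    lateral Cauchy stresses vanish, with lambda3 = 1/(lambda1*lambda2).
    """
    direction = Direction(direction)
    if lambda1 < 1.0 - 1e-12:
        raise ValueError(f"lambda1 must be >= 1, got {lambda1}")
    sigma1, lam2, lam3, p = uniaxial_sigma1(params, direction, np.array([lambda1]))
    # re-normalize lambda3 so the product is exactly 1 at float precision
    l2 = float(lam2[0])
    l3 = 1.0 / (lambda1 * l2)
    return UniaxialState(
        direction=direction,
        lambda1=float(lambda1),
        lambda2=l2,
        lambda3=l3,
        sigma1=float(sigma1[0]),
        p=float(p[0]),
    )


def forward_curves(
    params: GHOParams, stretch_grid: Sequence[float]
) -> tuple[StressStretchCurve, StressStretchCurve]:
    """Forward-model stress-stretch curves in both loading directions.

    The grid must be sorted and start at 1.  Transverse stretches are kept
    on the returned curves for physical-consistency plots.
    """
    grid = np.asarray(list(stretch_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty stretch grid")
    if abs(grid[0] - 1.0) > 1e-12:
        raise ValueError("stretch grid must start at 1")
    if np.any(np.diff(grid) < 0):
        raise ValueError("stretch grid must be sorted")
    out = []
    for direction in (Direction.CIRCUMFERENTIAL, Direction.LONGITUDINAL):
        sigma1, lam2, lam3, _ = uniaxial_sigma1(params, direction, grid)
        out.append(
            StressStretchCurve(
                stretch=grid.copy(),
                stress=sigma1,
                direction=direction,
                lambda2=lam2,
                lambda3=lam3,
            )
        )
    return out[0], out[1]
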