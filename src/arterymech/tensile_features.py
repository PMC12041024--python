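"""Processing of uniaxial tensile records into stress-stretch curves and
their characteristic descriptors.

A tensile record holds grip length vs force samples plus the specimen's
reference geometry (l0, w0, t0 in mm, force in N).  Under incompressibility
the instantaneous cross-section is A = A0/lambda1, so the Cauchy stress is

    sigma1 = F * lambda1 / (w0 * t0)      [N/mm^2 = MPa] -> x1000 kPa

The curve is truncated at the maximum-force sample (everything beyond is
post-rupture).  From the curve, six scalars are extracted: the low-strain
slope E1 and high-strain slope E2 (longest prefix/suffix whose linear fit
keeps r^2 >= 0.95), the elbow point (midpoint between the end of the E1
window and the start of the E2 window) and the rupture point (last sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .gho_constitutive import Direction, StressStretchCurve

__all__ = [
    "TensileRecord",
    "CurveFeatures",
    "compute_stress_stretch",
    "fit_terminal_slope",
    "extract_features",
    "FeatureExtractionError",
]

#: 1 N/mm^2 (MPa) expressed in kPa
KPA_PER_MPA = 1000.0

#: minimum number of points in a terminal-slope window
MIN_WINDOW = 4


class FeatureExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class TensileRecord:
    """Raw uniaxial tensile test: grip length (mm) vs force (N) samples."""

    direction: Direction
    l0: float  # reference gauge length, mm
    w0: float  # reference width, mm
    t0: float  # reference thickness, mm
    length_mm: np.ndarray
    force_N: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("l0", self.l0), ("w0", self.w0), ("t0", self.t0)):
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        l = np.asarray(self.length_mm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if l.shape != f.shape or l.ndim != 1 or l.size < 1:
            raise ValueError("length_mm and force_N must be equal-length 1-D arrays")
        if np.any(f < -1e-12):
            raise ValueError("negative force sample")
        object.__setattr__(self, "length_mm", l)
        object.__setattr__(self, "force_N", f)


@dataclass(frozen=True)
class CurveFeatures:
    """The six descriptors of a J-shaped stress-stretch curve (Table-style).

    E1/E2 in kPa (slopes d sigma/d lambda); elbow and rupture coordinates
    dimensionless stretch and kPa stress.  ``e1_window``/``e2_window`` are
    the index ranges (inclusive start, exclusive stop) used for the slope
    fits; ``degenerate`` flags overlapping windows (near-linear curves).
    """

    E1: float
    E2: float
    lambda_e: float
    sigma_e: float
    lambda_r: float
    sigma_r: float
    e1_window: tuple[int, int]
    e2_window: tuple[int, int]
    degenerate: bool = False


def compute_stress_stretch(record: TensileRecord) -> StressStretchCurve:
    """Convert a tensile record to a Cauchy stress (kPa) vs stretch curve.

    Samples are truncated at the maximum-force sample.  Raises on
    non-monotone grip length or zero cross-sectional area.
    """
    l = record.length_mm
    F = record.force_N
    if np.any(np.diff(l) < 0):
        raise ValueError("grip length must be non-decreasing")
    A0 = record.w0 * record.t0
    if A0 <= 0:
        raise ValueError("zero reference cross-sectional area")
    i_max = int(np.argmax(F))
    l, F = l[: i_max + 1], F[: i_max + 1]
    lam = l / record.l0
    sigma = F * lam / A0 * KPA_PER_MPA
    return StressStretchCurve(stretch=lam, stress=sigma, direction=record.direction)


def _ols_slope_r2(lam: np.ndarray, sig: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(lam, sig)
    return float(res.slope), float(res.rvalue**2)


#: residual-trimming cutoff: interior-end points whose |residual| exceeds
#: this multiple of the window's median |residual| are excluded.  3x leaves
#: smooth (quadratic-residual) windows untouched but expels points beyond a
#: sharp stiffness transition, where r^2 alone is insensitive.
TRIM_FACTOR = 3.0


def fit_terminal_slope(
    curve: StressStretchCurve,
    end: Literal["low", "high"],
    r2_min: float = 0.95,
) -> tuple[float, tuple[int, int]]:
    """Slope (kPa, d sigma/d lambda) of the longest terminal linear window.

    ``end='low'``: longest prefix starting at the first point whose OLS fit
    has r^2 >= r2_min; ``end='high'``: longest suffix ending at the rupture
    point.  Because r^2 is dominated by the window's overall variance, it
    barely reacts when a window leaks a few points past a sharp stiffness
    transition; the window is therefore refined by trimming interior-end
    points whose fit residual exceeds ``TRIM_FACTOR`` times the window's
    median absolute residual.  Windows shorter than 4 points are not
    considered.
    """
    n = len(curve)
    if n < MIN_WINDOW:
        raise FeatureExtractionError(f"need >= {MIN_WINDOW} points, got {n}")
    lam, sig = curve.stretch, curve.stress
    best: tuple[int, int] | None = None
    for size in range(n, MIN_WINDOW - 1, -1):
        if end == "low":
            i, j = 0, size
        else:
            i, j = n - size, n
        _, r2 = _ols_slope_r2(lam[i:j], sig[i:j])
        if r2 >= r2_min:
            best = (i, j)
            break
    if best is None:
        raise FeatureExtractionError(
            f"no {end}-end window of >= {MIN_WINDOW} points reaches r^2 >= {r2_min}"
        )
    i, j = best
    atol = 1e-9 * max(float(np.abs(sig).max()), 1.0)
    while j - i > MIN_WINDOW:
        res = stats.linregress(lam[i:j], sig[i:j])
        resid = sig[i:j] - (res.intercept + res.slope * lam[i:j])
        cut = max(TRIM_FACTOR * float(np.median(np.abs(resid))), atol)
        if end == "low":
            if abs(resid[-1]) > cut:
                j -= 1
                continue
        else:
            if abs(resid[0]) > cut:
                i += 1
                continue
        break
    slope, _ = _ols_slope_r2(lam[i:j], sig[i:j])
    return slope, (i, j)


def extract_features(
    curve: StressStretchCurve, r2_min: float = 0.95
) -> CurveFeatures:
    """Extract E1, E2, elbow and rupture point from a stress-stretch curve.

    The elbow is the mean stress-stretch coordinate between the last point
    of the E1 window and the first point of the E2 window.  If the windows
    overlap (near-linear curve) the elbow degenerates to the midpoint of the
    overlap and the result is flagged.
    """
    E1, w1 = fit_terminal_slope(curve, "low", r2_min)
    E2, w2 = fit_terminal_slope(curve, "high", r2_min)
    lam, sig = curve.stretch, curve.stress
    i_end = w1[1] - 1  # last index of E1 window
    j_start = w2[0]  # first index of E2 window
    # a shared boundary point is a clean transition; only a true overlap
    # (near-linear curve) degenerates
    degenerate = i_end > j_start
    if degenerate:
        a, b = j_start, i_end
    else:
        a, b = i_end, j_start
    lam_e = 0.5 * (lam[a] + lam[b])
    sig_e = 0.5 * (sig[a] + sig[b])
    return CurveFeatures(
        E1=E1,
        E2=E2,
        lambda_e=float(lam_e),
        sigma_e=float(sig_e),
        lambda_r=float(lam[-1]),
        sigma_r=float(sig[-1]),
        e1_window=w1,
        e2_window=w2,
        degenerate=degenerate,
    )
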