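"""Identification of GHO constants from paired uniaxial tensile curves.

Both loading directions (circumferential and longitudinal) are fitted
simultaneously by bounded nonlinear least squares on the stacked Cauchy
stress residuals.  Because the fiber exponential constants (k1, k2) trade
off strongly, the solver is restarted from a seeded low-discrepancy (Sobol)
sequence of initial guesses over the bounded box and the best converged
solution is kept; starts stop early once a numerically perfect fit is found.

Goodness of fit is reported per direction as r^2 = 1 - SSres/SStot on the
stresses, and physical consistency as monotone decay of the transverse
stretches lambda2(lambda1), lambda3(lambda1) in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .gho_constitutive import (
    ConvergenceError,
    Direction,
    GHOParams,
    StressStretchCurve,
    uniaxial_sigma1,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "fit_gho",
    "r_squared",
    "check_physical_consistency",
]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Multi-start least-squares settings.

    Bounds: mu, k1 in kPa, k2 dimensionless, kappa in [0, 1/3], gamma in
    degrees from the longitudinal axis.  ``n_starts`` Sobol points over the
    start box are tried in sequence (seeded, reproducible); iteration stops
    early when the relative objective falls below ``perfect_tol``.
    """

    n_starts: int = 16
    seed: int = 7
    bounds_lo: tuple[float, ...] = (1e-3, 0.0, 1e-6, 0.0, 0.0)
    bounds_hi: tuple[float, ...] = (500.0, 500.0, 5.0, 1.0 / 3.0, 90.0)
    start_lo: tuple[float, ...] = (5.0, 5.0, 0.01, 0.01, 5.0)
    start_hi: tuple[float, ...] = (150.0, 300.0, 1.0, 0.32, 85.0)
    perfect_tol: float = 1e-12
    max_nfev: int = 400
    fiber_tension_only: bool = False


@dataclass(frozen=True)
class FitResult:
    params: GHOParams
    r2_circ: float
    r2_long: float
    objective: float  # sum of squared stress residuals, kPa^2
    n_starts: int
    consistent: bool

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(
            r2_circ=self.r2_circ,
            r2_long=self.r2_long,
            objective_kPa2=self.objective,
            n_starts=self.n_starts,
            consistent=self.consistent,
        )
        return d


def r_squared(model_stress, data_stress) -> float:
    """Coefficient of determination 1 - SSres/SStot on stresses."""
    m = np.asarray(model_stress, dtype=float)
    d = np.asarray(data_stress, dtype=float)
    if m.shape != d.shape or d.ndim != 1 or d.size < 2:
        raise ValueError("model and data must be equal-length 1-D arrays, n >= 2")
    sstot = float(np.sum((d - d.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("r^2 undefined for constant data")
    return 1.0 - float(np.sum((d - m) ** 2)) / sstot


def _params_from_vector(x: np.ndarray, tension_only: bool) -> GHOParams:
    mu, k1, k2, kappa, gamma = (float(v) for v in x)
    return GHOParams(
        mu=max(mu, 1e-9),
        k1=max(k1, 0.0),
        k2=max(k2, 1e-9),
        kappa=min(max(kappa, 0.0), 1.0 / 3.0),
        gamma=min(max(gamma, 0.0), 90.0),
        fiber_tension_only=tension_only,
    )


def _residuals(
    x: np.ndarray,
    lam_c: np.ndarray,
    sig_c: np.ndarray,
    lam_l: np.ndarray,
    sig_l: np.ndarray,
    tension_only: bool,
) -> np.ndarray:
    params = _params_from_vector(x, tension_only)
    try:
        mc, _, _, _ = uniaxial_sigma1(params, Direction.CIRCUMFERENTIAL, lam_c)
        ml, _, _, _ = uniaxial_sigma1(params, Direction.LONGITUDINAL, lam_l)
    except ConvergenceError:
        return np.full(lam_c.size + lam_l.size, 1e6)
    res = np.concatenate([mc - sig_c, ml - sig_l])
    if not np.all(np.isfinite(res)):
        return np.full(res.size, 1e6)
    return res


def fit_gho(
    curve_circ: StressStretchCurve,
    curve_long: StressStretchCurve,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the five GHO constants to a circumferential/longitudinal curve pair.

    Minimizes the total squared stress residual over both directions with a
    trust-region (Levenberg-Marquardt type) solver under box bounds, best of
    ``config.n_starts`` seeded Sobol starts.
    """
    cfg = config or FitConfig()
    if len(curve_circ) == 0 or len(curve_long) == 0:
        raise ValueError("both curves must be non-empty")
    lam_c, sig_c = curve_circ.stretch, curve_circ.stress
    lam_l, sig_l = curve_long.stretch, curve_long.stress
    if np.any(lam_c < 1 - 1e-9) or np.any(lam_l < 1 - 1e-9):
        raise ValueError("stretches must be >= 1")

    sstot = float(np.sum((sig_c - sig_c.mean()) ** 2) + np.sum((sig_l - sig_l.mean()) ** 2))
    sampler = qmc.Sobol(d=5, scramble=True, seed=cfg.seed)
    s_lo, s_hi = np.asarray(cfg.start_lo), np.asarray(cfg.start_hi)
    # manual affine scaling tolerates a collapsed (single-point) start box
    starts = s_lo + sampler.random(cfg.n_starts) * (s_hi - s_lo)

    lo = np.asarray(cfg.bounds_lo)
    hi = np.asarray(cfg.bounds_hi)
    x_scale = np.array([10.0, 10.0, 0.1, 0.05, 10.0])
    best = None
    diagnostics = []
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            sol = least_squares(
                _residuals,
                np.clip(x0, lo, hi),
                args=(lam_c, sig_c, lam_l, sig_l, cfg.fiber_tension_only),
                bounds=(lo, hi),
                method="trf",
                x_scale=x_scale,
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=cfg.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failure
            diagnostics.append(str(exc))
            continue
        cost = float(2.0 * sol.cost)  # sum of squared residuals
        if best is None or cost < best[0]:
            best = (cost, sol.x)
        if sstot > 0 and cost <= cfg.perfect_tol * sstot:
            break
    if best is None:
        raise FitError("all starts failed to converge: " + "; ".join(diagnostics))

    objective, x = best
    params = _params_from_vector(x, cfg.fiber_tension_only)
    mc, _, _, _ = uniaxial_sigma1(params, Direction.CIRCUMFERENTIAL, lam_c)
    ml, _, _, _ = uniaxial_sigma1(params, Direction.LONGITUDINAL, lam_l)
    grid = np.unique(np.concatenate([lam_c, lam_l]))
    consistent, _ = check_physical_consistency(params, grid)
    return FitResult(
        params=params,
        r2_circ=r_squared(mc, sig_c),
        r2_long=r_squared(ml, sig_l),
        objective=objective,
        n_starts=n_used,
        consistent=consistent,
    )


def check_physical_consistency(
    params: GHOParams, stretch_grid
) -> tuple[bool, dict[str, np.ndarray]]:
    """True iff lambda2 and lambda3 strictly decrease with the applied
    stretch in both loading directions over the grid.

    Returns the verdict and the transverse-stretch table used for it
    (keys ``lambda1``, ``lambda2_<dir>``, ``lambda3_<dir>``).
    """
    grid = np.asarray(stretch_grid, dtype=float)
    table: dict[str, np.ndarray] = {"lambda1": grid}
    ok = True
    for direction in (Direction.CIRCUMFERENTIAL, Direction.LONGITUDINAL):
        _, lam2, lam3, _ = uniaxial_sigma1(params, direction, grid)
        table[f"lambda2_{direction.value}"] = lam2
        table[f"lambda3_{direction.value}"] = lam3
        if grid.size >= 2:
            ok = ok and bool(np.all(np.diff(lam2) < 0) and np.all(np.diff(lam3) < 0))
    return ok, table
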