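"""End-to-end study orchestration.

Runs the full analysis in the order of the experimental protocol:

1. tensile records -> stress-stretch curves -> per-specimen descriptors
   (low/high-strain slopes, elbow, rupture) with group statistics;
2. group-mean curves (pointwise mean of per-specimen curves linearly
   interpolated onto a common 100-point stretch grid, up to the smallest
   rupture stretch in the group) -> GHO constitutive fit per group;
3. group-mean ring geometry + fitted constants -> residual-stress closure
   solve (inner/outer hoop stress and their difference);
4. histology phantoms -> fiber fractions, nuclei density, layer shares,
   with group statistics.

Every stage is individually toggleable; all randomness is seeded through
the cohort spec and fit config, so a given configuration reproduces its
report tables byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gho_constitutive import Direction, StressStretchCurve
from .group_stats import compare, summarize
from .histomorphometry import area_fractions, count_nuclei, layer_percentages
from .ring_residual_stress import RingGeometry, ResidualStressProfile, solve_closure
from .synthetic_data import CohortData, CohortSpec, Specimen, gen_cohort
from .tensile_features import compute_stress_stretch, extract_features
from .uniaxial_fitting import FitConfig, FitResult, fit_gho

__all__ = ["StudyConfig", "StudyReport", "run_study", "mean_group_curve"]

log = logging.getLogger("arterymech")


@dataclass(frozen=True)
class StudyConfig:
    cohort: CohortSpec | None = None  # None -> default synthetic cohort
    fit: FitConfig = field(default_factory=FitConfig)
    do_features: bool = True
    do_fitting: bool = True
    do_residual_stress: bool = True
    do_histology: bool = True
    n_mean_grid: int = 100
    r2_min: float = 0.95
    alpha_level: float = 0.05
    make_plots: bool = False


@dataclass
class StudyReport:
    """Report bundle: one DataFrame per analogue of the study's tables."""

    features: pd.DataFrame | None = None
    features_summary: pd.DataFrame | None = None
    gho_fits: pd.DataFrame | None = None
    fit_results: dict[str, FitResult] = field(default_factory=dict)
    residual_stress: pd.DataFrame | None = None
    residual_profiles: dict[str, ResidualStressProfile] = field(default_factory=dict)
    histology: pd.DataFrame | None = None
    histology_summary: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "features.csv": self.features,
            "features_summary.csv": self.features_summary,
            "gho_fits.csv": self.gho_fits,
            "residual_stress.csv": self.residual_stress,
            "histology.csv": self.histology,
            "histology_summary.csv": self.histology_summary,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(out / name, index=False, float_format="%.10g")
        if self.fit_results:
            payload = {g: r.to_dict() for g, r in self.fit_results.items()}
            (out / "gho_fits.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))
        for g, prof in self.residual_profiles.items():
            pd.DataFrame(
                {
                    "r_mm": prof.radii,
                    "sigma_r_kPa": prof.sigma_r,
                    "sigma_theta_kPa": prof.sigma_theta,
                }
            ).to_csv(out / f"residual_profile_{g}.csv", index=False, float_format="%.10g")


def mean_group_curve(
    curves: list[StressStretchCurve], n_grid: int = 100
) -> StressStretchCurve:
    """Pointwise mean of curves on a common linear stretch grid.

    The grid spans [1, min over curves of max stretch] so every specimen
    contributes at every grid point.
    """
    if not curves:
        raise ValueError("no curves to average")
    lam_max = min(float(c.stretch[-1]) for c in curves)
    grid = np.linspace(1.0, lam_max, n_grid)
    stacked = np.stack([np.interp(grid, c.stretch, c.stress) for c in curves])
    return StressStretchCurve(
        stretch=grid, stress=stacked.mean(axis=0), direction=curves[0].direction
    )


_FEATURE_COLS = ("E1", "E2", "lambda_e", "sigma_e", "lambda_r", "sigma_r")


def _features_stage(cohort: CohortData, cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for s in cohort.specimens:
        for rec in (s.tensile_circ, s.tensile_long):
            curve = compute_stress_stretch(rec)
            f = extract_features(curve, cfg.r2_min)
            rows.append(
                {
                    "specimen": s.specimen_id,
                    "group": s.group,
                    "direction": rec.direction.value,
                    "E1": f.E1,
                    "E2": f.E2,
                    "lambda_e": f.lambda_e,
                    "sigma_e": f.sigma_e,
                    "lambda_r": f.lambda_r,
                    "sigma_r": f.sigma_r,
                    "degenerate": f.degenerate,
                }
            )
    features = pd.DataFrame(rows)
    long = features.melt(
        id_vars=["specimen", "group", "direction"],
        value_vars=list(_FEATURE_COLS),
        var_name="variable",
    )
    summary = _summarize_long(long, by=["direction", "variable"], alpha=cfg.alpha_level)
    return features, summary


def _summarize_long(long: pd.DataFrame, by: list[str], alpha: float) -> pd.DataFrame:
    """Mean ± SEM + CI per group and the decision-tree p-value per variable."""
    rows = []
    groups = sorted(long["group"].unique())
    for keys, sub in long.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        samples = {}
        for g in groups:
            vals = sub.loc[sub["group"] == g, "value"].to_numpy()
            samples[g] = vals
            summ = summarize(vals)
            row.update(
                {
                    f"{g}_n": summ.n,
                    f"{g}_mean": summ.mean,
                    f"{g}_sem": summ.sem,
                    f"{g}_ci_low": summ.ci_low,
                    f"{g}_ci_high": summ.ci_high,
                }
            )
        if len(groups) == 2:
            try:
                res = compare(samples[groups[0]], samples[groups[1]], alpha=alpha)
            except ValueError as exc:  # constant groups (degenerate synthetic data)
                log.warning("compare %s skipped: %s", row.get("variable"), exc)
                row.update(test_used="none", p_value=np.nan, significant=False,
                           mean_difference=float(samples[groups[0]].mean() - samples[groups[1]].mean()))
            else:
                row.update(
                    test_used=res.test_used.value,
                    p_value=res.p_value,
                    significant=res.significant,
                    mean_difference=res.mean_difference,
                )
                log.info("compare %s: %s -> p=%.3g", row.get("variable"), res.test_used.value, res.p_value)
        rows.append(row)
    return pd.DataFrame(rows)


def _fitting_stage(cohort: CohortData, cfg: StudyConfig) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    rows = []
    results: dict[str, FitResult] = {}
    for gspec in cohort.spec.groups:
        members = cohort.group(gspec.name)
        circ = mean_group_curve(
            [compute_stress_stretch(s.tensile_circ) for s in members], cfg.n_mean_grid
        )
        lng = mean_group_curve(
            [compute_stress_stretch(s.tensile_long) for s in members], cfg.n_mean_grid
        )
        log.info("fitting GHO constants for group %s (%d starts)", gspec.name, cfg.fit.n_starts)
        res = fit_gho(circ, lng, cfg.fit)
        results[gspec.name] = res
        rows.append({"group": gspec.name, **res.to_dict()})
    return pd.DataFrame(rows), results


def _residual_stage(
    cohort: CohortData, fits: dict[str, FitResult]
) -> tuple[pd.DataFrame, dict[str, ResidualStressProfile]]:
    rows = []
    profiles: dict[str, ResidualStressProfile] = {}
    for gspec in cohort.spec.groups:
        members = cohort.group(gspec.name)
        geom = RingGeometry(
            Ro=float(np.mean([s.ring.Ro for s in members])),
            to=float(np.mean([s.ring.to for s in members])),
            alpha=float(np.mean([s.ring.alpha for s in members])),
        )
        prof = solve_closure(geom, fits[gspec.name].params)
        profiles[gspec.name] = prof
        rows.append(
            {
                "group": gspec.name,
                "Ro_mm": geom.Ro,
                "to_mm": geom.to,
                "alpha_deg": geom.alpha,
                "sigma_theta_in_kPa": prof.sigma_theta_in,
                "sigma_theta_out_kPa": prof.sigma_theta_out,
                "delta_sigma_theta_kPa": prof.delta_sigma_theta,
            }
        )
    return pd.DataFrame(rows), profiles


def _histology_stage(cohort: CohortData, cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for s in cohort.specimens:
        elastic, collagen = area_fractions(s.vge)
        _, density = count_nuclei(s.he)
        im_pct, ad_pct, t_mm = layer_percentages(s.boundaries, s.morpho_scale_um_per_px)
        rows.append(
            {
                "specimen": s.specimen_id,
                "group": s.group,
                "Ro_mm": s.ring.Ro,
                "to_mm": t_mm,
                "alpha_deg": s.ring.alpha,
                "intima_media_pct": im_pct,
                "adventitia_pct": ad_pct,
                "elastic_pct": elastic,
                "collagen_pct": collagen,
                "nuclei_per_mm2": density,
            }
        )
    histo = pd.DataFrame(rows)
    long = histo.melt(id_vars=["specimen", "group"], var_name="variable")
    summary = _summarize_long(long, by=["variable"], alpha=cfg.alpha_level)
    return histo, summary


def run_study(config: StudyConfig | None = None, out_dir: str | Path | None = None) -> StudyReport:
    """Run the configured stages on the (synthetic) cohort and return the
    report bundle; optionally write its tables under ``out_dir``."""
    cfg = config or StudyConfig()
    report = StudyReport()
    if not (cfg.do_features or cfg.do_fitting or cfg.do_residual_stress or cfg.do_histology):
        log.info("all stages disabled: empty report")
        return report
    cohort = gen_cohort(cfg.cohort)
    log.info("cohort: %d specimens in %d groups", len(cohort.specimens), len(cfg.cohort.groups) if cfg.cohort else 2)

    if cfg.do_features:
        report.features, report.features_summary = _features_stage(cohort, cfg)
    if cfg.do_fitting or cfg.do_residual_stress:
        report.gho_fits, report.fit_results = _fitting_stage(cohort, cfg)
    if cfg.do_residual_stress:
        report.residual_stress, report.residual_profiles = _residual_stage(
            cohort, report.fit_results
        )
    if cfg.do_histology:
        report.histology, report.histology_summary = _histology_stage(cohort, cfg)
    if out_dir is not None:
        report.write(out_dir)
        if cfg.make_plots:
            _write_plots(report, cohort, cfg, Path(out_dir))
    return report


def _write_plots(report: StudyReport, cohort: CohortData, cfg: StudyConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.fit_results:
        from .gho_constitutive import forward_curves

        fig, axes = plt.subplots(1, len(report.fit_results), figsize=(5 * len(report.fit_results), 4))
        axes = np.atleast_1d(axes)
        for ax, (gname, res) in zip(axes, report.fit_results.items()):
            members = cohort.group(gname)
            for s in members:
                for rec, style in ((s.tensile_circ, "C0."), (s.tensile_long, "C1.")):
                    c = compute_stress_stretch(rec)
                    ax.plot(c.stretch, c.stress, style, ms=2, alpha=0.3)
            lam_max = min(
                float(compute_stress_stretch(s.tensile_circ).stretch[-1]) for s in members
            )
            grid = np.linspace(1.0, lam_max, 60)
            cc, cl = forward_curves(res.params, grid)
            ax.plot(cc.stretch, cc.stress, "C0-", label="circumferential fit")
            ax.plot(cl.stretch, cl.stress, "C1-", label="longitudinal fit")
            ax.set_xlabel(r"stretch $\lambda_1$")
            ax.set_ylabel(r"Cauchy stress $\sigma_1$ [kPa]")
            ax.set_title(gname)
            ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fits.png", dpi=120)
        plt.close(fig)
    if report.residual_profiles:
        fig, ax = plt.subplots(figsize=(5, 4))
        for gname, prof in report.residual_profiles.items():
            ax.plot(prof.radii, prof.sigma_theta, label=f"{gname} hoop")
            ax.plot(prof.radii, prof.sigma_r, "--", label=f"{gname} radial")
        ax.set_xlabel("closed-configuration radius [mm]")
        ax.set_ylabel("residual stress [kPa]")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "residual_stress.png", dpi=120)
        plt.close(fig)
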