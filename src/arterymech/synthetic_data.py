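"""Seeded synthetic study data with known ground truth.

Emulates a two-group arterial biomechanics study (control n = 6, treated
n = 5): per specimen it generates (a) uniaxial tensile force-length records
in both loading directions from the group's ground-truth GHO constants plus
multiplicative measurement noise and a rupture cutoff, (b) ring morphometry
(luminal radius, wall thickness, opening angle) drawn from the group
means/SEMs, (c) histology-like phantom images painted with the reference
stain colors at known fiber fractions and nucleus counts, and (d) concentric
wall-boundary annotations realising a known intima-media share.

Group standard deviations are derived from the published standard errors as
sd = SEM * sqrt(n).  Every artifact is reproducible from (spec, seed) alone
and each specimen carries a ground-truth manifest entry, so downstream
recovery tests are self-auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gho_constitutive import Direction, GHOParams, uniaxial_sigma1
from .histomorphometry import HistologyImage, Stain
from .ring_residual_stress import RingGeometry
from .tensile_features import TensileRecord

__all__ = [
    "SpecimenGeometry",
    "Normal",
    "GroupSpec",
    "CohortSpec",
    "Specimen",
    "CohortData",
    "default_cohort_spec",
    "gen_tensile_record",
    "gen_vge_phantom",
    "gen_he_phantom",
    "he_phantom_capacity",
    "zero_variance_spec",
    "gen_wall_boundaries",
    "gen_cohort",
]

# reference stain colors used by the phantoms; they sit inside the default
# HSB windows of the histomorphometry module, so fraction/count recovery is
# threshold-independent by construction
ELASTIC_RGB = (0.0, 0.0, 0.0)
COLLAGEN_RGB = (0.90, 0.40, 0.55)
NUCLEI_RGB = (0.45, 0.25, 0.60)
BACKGROUND_RGB = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Reference geometry of one rectangular tensile specimen (mm)."""

    l0: float = 10.0
    w0: float = 4.0
    t0: float = 0.5


@dataclass(frozen=True)
class Normal:
    """A group-level normal variable parameterized by mean and SEM."""

    mean: float
    sem: float

    def sd(self, n: int) -> float:
        return self.sem * math.sqrt(n)


@dataclass(frozen=True)
class GroupSpec:
    """Ground truth and sampling distributions for one study group."""

    name: str
    n: int
    gho: GHOParams
    Ro_mm: Normal
    to_mm: Normal
    alpha_deg: Normal
    elastic_pct: Normal
    collagen_pct: Normal
    nuclei_per_mm2: Normal
    intima_media_pct: Normal
    rupture_circ: Normal
    rupture_long: Normal

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 42
    noise_rel: float = 0.01  # multiplicative force noise (1 sd)
    n_tensile_samples: int = 120
    vge_size_px: int = 160
    he_size_px: int = 256
    he_scale_um_per_px: float = 1.6
    morpho_scale_um_per_px: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise level must be >= 0")


def default_cohort_spec(seed: int = 42, noise_rel: float = 0.01) -> CohortSpec:
    """The default two-group cohort: control (CN, n=6) vs melatonin (MN, n=5).

    Ground-truth GHO rows, geometry, opening angles and histology targets
    are the published group means/SEMs of the lamb carotid study this
    pipeline reproduces.
    """
    cn = GroupSpec(
        name="CN",
        n=6,
        gho=GHOParams(mu=35.0, k1=73.0, k2=0.07, kappa=0.27, gamma=74.5),
        Ro_mm=Normal(1.28, 0.07),
        to_mm=Normal(0.53, 0.04),
        alpha_deg=Normal(111.0, 15.0),
        elastic_pct=Normal(31.3, 3.7),
        collagen_pct=Normal(7.0, 0.9),
        nuclei_per_mm2=Normal(2524.0, 66.0),
        intima_media_pct=Normal(52.7, 2.7),
        rupture_circ=Normal(2.25, 0.10),
        rupture_long=Normal(2.73, 0.14),
    )
    mn = GroupSpec(
        name="MN",
        n=5,
        gho=GHOParams(mu=33.0, k1=79.0, k2=0.06, kappa=0.26, gamma=52.5),
        Ro_mm=Normal(1.14, 0.04),
        to_mm=Normal(0.48, 0.06),
        alpha_deg=Normal(124.0, 16.0),
        elastic_pct=Normal(39.6, 3.2),
        collagen_pct=Normal(6.8, 0.1),
        nuclei_per_mm2=Normal(2570.0, 142.0),
        intima_media_pct=Normal(54.7, 2.1),
        rupture_circ=Normal(2.31, 0.15),
        rupture_long=Normal(2.59, 0.05),
    )
    return CohortSpec(groups=(cn, mn), seed=seed, noise_rel=noise_rel)


# ----------------------------------------------------------------------------
# tensile records
# ----------------------------------------------------------------------------

def gen_tensile_record(
    params: GHOParams,
    geometry: SpecimenGeometry,
    direction: Direction | str,
    rupture_stretch: float,
    noise_rel: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_samples: int = 120,
) -> TensileRecord:
    """Synthesize a force-length tensile record from the GHO forward model.

    Force samples F = sigma1 * (w0*t0) / lambda1 on a uniform grip-length
    grid from l0 to l0*rupture_stretch, each multiplied by
    (1 + noise_rel * eps) with seeded standard-normal eps.
    """
    if rupture_stretch <= 1.0:
        raise ValueError("rupture stretch must exceed 1")
    direction = Direction(direction)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.linspace(1.0, rupture_stretch, n_samples)
    sigma, _, _, _ = uniaxial_sigma1(params, direction, lam)
    area0 = geometry.w0 * geometry.t0
    force = sigma * 1e-3 * area0 / lam  # kPa -> N/mm^2 conversion
    if noise_rel > 0:
        force = force * (1.0 + noise_rel * rng.standard_normal(force.shape))
        force = np.maximum(force, 0.0)
    return TensileRecord(
        direction=direction,
        l0=geometry.l0,
        w0=geometry.w0,
        t0=geometry.t0,
        length_mm=lam * geometry.l0,
        force_N=force,
    )


# ----------------------------------------------------------------------------
# histology phantoms
# ----------------------------------------------------------------------------

def gen_vge_phantom(
    elastic_pct: float,
    collagen_pct: float,
    size_px: int = 160,
    scale_um_per_px: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> HistologyImage:
    """VGE-like phantom: exact pixel fractions of elastic black and collagen
    pink scattered over a white background."""
    if elastic_pct < 0 or collagen_pct < 0 or elastic_pct + collagen_pct > 100:
        raise ValueError("fractions must be non-negative and sum to <= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = size_px * size_px
    n_el = round(elastic_pct / 100.0 * n)
    n_col = round(collagen_pct / 100.0 * n)
    idx = rng.permutation(n)
    img = np.empty((n, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    img[idx[:n_el]] = ELASTIC_RGB
    img[idx[n_el : n_el + n_col]] = COLLAGEN_RGB
    return HistologyImage(
        pixels=img.reshape(size_px, size_px, 3),
        scale_um_per_px=scale_um_per_px,
        stain=Stain.VGE,
    )


def _disk_offsets(radius_px: float) -> np.ndarray:
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 <= radius_px**2
    return np.stack([yy[inside], xx[inside]], axis=1)


def _he_grid(size_px: int, radius_px: float) -> list[tuple[int, int]]:
    # pitch leaves >= 1 empty pixel between disk bounding boxes, so separate
    # particles never merge under 8-connectivity
    pitch = 2 * int(radius_px) + 2
    margin = pitch
    centers_1d = np.arange(margin, size_px - margin, pitch)
    return [(int(y), int(x)) for y in centers_1d for x in centers_1d]


def he_phantom_capacity(size_px: int = 256, nucleus_radius_px: float = 4.2) -> int:
    """Maximum number of particles a phantom of this size can hold."""
    return len(_he_grid(size_px, nucleus_radius_px))


def gen_he_phantom(
    n_nuclei: int,
    size_px: int = 256,
    scale_um_per_px: float = 1.6,
    nucleus_radius_px: float = 4.2,
    n_specks: int = 0,
    speck_radius_px: float = 2.3,
    seed: int | np.random.Generator = 0,
) -> HistologyImage:
    """HE-like phantom: ``n_nuclei`` purple disks (plus optional sub-floor
    specks) on a seeded random subset of grid cells, non-overlapping."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = _he_grid(size_px, max(nucleus_radius_px, speck_radius_px))
    if n_nuclei + n_specks > len(cells):
        raise ValueError(
            f"cannot place {n_nuclei + n_specks} particles on a "
            f"{len(cells)}-cell grid; enlarge the image"
        )
    order = rng.permutation(len(cells))
    img = np.ones((size_px, size_px, 3), dtype=float)
    disk = _disk_offsets(nucleus_radius_px)
    speck = _disk_offsets(speck_radius_px)
    for k in range(n_nuclei + n_specks):
        cy, cx = cells[order[k]]
        offs = disk if k < n_nuclei else speck
        img[cy + offs[:, 0], cx + offs[:, 1]] = NUCLEI_RGB
    return HistologyImage(
        pixels=img, scale_um_per_px=scale_um_per_px, stain=Stain.HE
    )


def gen_wall_boundaries(
    Ro_mm: float,
    to_mm: float,
    intima_media_pct: float,
    scale_um_per_px: float = 2.0,
    n_vertices: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three concentric circular boundary polylines (px) realising a known
    intima-media share of the wall thickness."""
    r1 = Ro_mm * 1000.0 / scale_um_per_px
    r2 = (Ro_mm + intima_media_pct / 100.0 * to_mm) * 1000.0 / scale_um_per_px
    r3 = (Ro_mm + to_mm) * 1000.0 / scale_um_per_px
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    c = r3 + 2.0
    return tuple(
        np.stack([c + r * np.cos(phi), c + r * np.sin(phi)], axis=1)
        for r in (r1, r2, r3)
    )


# ----------------------------------------------------------------------------
# cohort assembly
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class Specimen:
    """One synthetic animal: inputs for every pipeline stage + ground truth."""

    specimen_id: str
    group: str
    tensile_circ: TensileRecord
    tensile_long: TensileRecord
    ring: RingGeometry
    vge: HistologyImage
    he: HistologyImage
    boundaries: tuple[np.ndarray, np.ndarray, np.ndarray]
    morpho_scale_um_per_px: float
    truth: dict


@dataclass(frozen=True)
class CohortData:
    spec: CohortSpec
    specimens: tuple[Specimen, ...]
    manifest: pd.DataFrame = field(repr=False)

    def group(self, name: str) -> list[Specimen]:
        return [s for s in self.specimens if s.group == name]


def _draw_positive(rng: np.random.Generator, var: Normal, n: int, lo: float, hi: float) -> float:
    """Normal draw with sd = SEM*sqrt(n), resampled into (lo, hi); errors
    after 100 attempts (impossible target)."""
    sd = var.sd(n)
    for _ in range(100):
        x = rng.normal(var.mean, sd)
        if lo < x < hi:
            return float(x)
    raise ValueError(f"could not draw a value in ({lo}, {hi}) from {var}")


def gen_cohort(spec: CohortSpec | None = None) -> CohortData:
    """Generate the full study bundle for every specimen of every group."""
    spec = spec or default_cohort_spec()
    root = np.random.default_rng(spec.seed)
    specimens: list[Specimen] = []
    rows: list[dict] = []
    for g in spec.groups:
        for i in range(g.n):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            Ro = _draw_positive(rng, g.Ro_mm, g.n, 0.05, 10.0)
            to = _draw_positive(rng, g.to_mm, g.n, 0.02, 5.0)
            alpha = _draw_positive(rng, g.alpha_deg, g.n, 0.0, 179.0)
            elastic = _draw_positive(rng, g.elastic_pct, g.n, 0.0, 80.0)
            collagen = _draw_positive(rng, g.collagen_pct, g.n, 0.0, 80.0)
            he_area_mm2 = (spec.he_size_px * spec.he_scale_um_per_px / 1000.0) ** 2
            max_density = 0.95 * he_phantom_capacity(spec.he_size_px) / he_area_mm2
            nuclei = _draw_positive(rng, g.nuclei_per_mm2, g.n, 100.0, max_density)
            im_pct = _draw_positive(rng, g.intima_media_pct, g.n, 5.0, 95.0)
            rup_c = _draw_positive(rng, g.rupture_circ, g.n, 1.2, 5.0)
            rup_l = _draw_positive(rng, g.rupture_long, g.n, 1.2, 5.0)

            geom = SpecimenGeometry(l0=10.0, w0=4.0, t0=to)
            rec_c = gen_tensile_record(
                g.gho, geom, Direction.CIRCUMFERENTIAL, rup_c,
                spec.noise_rel, rng, spec.n_tensile_samples,
            )
            rec_l = gen_tensile_record(
                g.gho, geom, Direction.LONGITUDINAL, rup_l,
                spec.noise_rel, rng, spec.n_tensile_samples,
            )
            ring = RingGeometry(Ro=Ro, to=to, alpha=alpha)
            vge = gen_vge_phantom(elastic, collagen, spec.vge_size_px, seed=rng)
            n_nuc = int(round(nuclei * he_area_mm2))
            he = gen_he_phantom(
                n_nuc, spec.he_size_px, spec.he_scale_um_per_px, seed=rng
            )
            bounds = gen_wall_boundaries(Ro, to, im_pct, spec.morpho_scale_um_per_px)
            sid = f"{g.name}-{i + 1:02d}"
            truth = {
                "Ro_mm": Ro,
                "to_mm": to,
                "alpha_deg": alpha,
                "elastic_pct": elastic,
                "collagen_pct": collagen,
                "nuclei_per_mm2": nuclei,
                "n_nuclei_painted": n_nuc,
                "intima_media_pct": im_pct,
                "rupture_circ": rup_c,
                "rupture_long": rup_l,
                **g.gho.to_dict(),
            }
            specimens.append(
                Specimen(
                    specimen_id=sid,
                    group=g.name,
                    tensile_circ=rec_c,
                    tensile_long=rec_l,
                    ring=ring,
                    vge=vge,
                    he=he,
                    boundaries=bounds,
                    morpho_scale_um_per_px=spec.morpho_scale_um_per_px,
                    truth=truth,
                )
            )
            rows.extend(
                {"specimen": sid, "group": g.name, "variable": k, "value": v}
                for k, v in truth.items()
            )
    manifest = pd.DataFrame(rows)
    return CohortData(spec=spec, specimens=tuple(specimens), manifest=manifest)


def zero_variance_spec(seed: int = 42, noise_rel: float = 0.0) -> CohortSpec:
    """Default cohort with all group SEMs zeroed (every specimen identical
    to its group mean); handy for deterministic end-to-end checks."""
    base = default_cohort_spec(seed=seed, noise_rel=noise_rel)
    groups = []
    for g in base.groups:
        kw = {}
        for f in (
            "Ro_mm", "to_mm", "alpha_deg", "elastic_pct", "collagen_pct",
            "nuclei_per_mm2", "intima_media_pct", "rupture_circ", "rupture_long",
        ):
            kw[f] = Normal(getattr(g, f).mean, 0.0)
        groups.append(replace(g, **kw))
    return replace(base, groups=tuple(groups), noise_rel=noise_rel)
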