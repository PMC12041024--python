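"""Quantification of stained arterial cross-sections.

Two stains are analysed.  Hematoxylin-Eosin (HE) shows cell nuclei in
purple: nuclei are segmented by HSB (hue/saturation/brightness) color
thresholding and counted with a particle analyser that keeps 8-connected
components of at least 50 px² (density = count per mm² of ROI).  Van Gieson
Elastic (VGE) shows elastic fibers black and collagen pink: both are
thresholded in HSB and reported as a percentage of the ROI (media layer)
area, with the black (elastic) test taking precedence over pink on
overlapping assignments.

Morphometry comes from three annotated wall boundaries (lumen, internal
elastic boundary between media and adventitia, outer edge): mean radial
distances between consecutive boundaries give the intima-media and
adventitia shares of the wall thickness and the total thickness in mm.

The exact HSB windows of the original ImageJ workflow are not published;
the reference windows shipped here (`DEFAULT_RANGES`) are configuration,
chosen to isolate the canonical stain colors, never a reproduction claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage import color, measure

__all__ = [
    "Stain",
    "HSBRange",
    "HistologyImage",
    "HistoQuant",
    "DEFAULT_RANGES",
    "threshold_hsb",
    "count_nuclei",
    "area_fractions",
    "layer_percentages",
]


class Stain(str, Enum):
    HE = "HE"
    VGE = "VGE"


@dataclass(frozen=True)
class HSBRange:
    """Closed HSB intervals in [0, 1]; the hue interval is circular.

    A hue interval with ``hue[0] > hue[1]`` wraps through 0 (selects reds on
    both sides of the wrap point).
    """

    hue: tuple[float, float]
    saturation: tuple[float, float]
    brightness: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("hue", self.hue),
            ("saturation", self.saturation),
            ("brightness", self.brightness),
        ):
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ValueError(f"{name} interval must lie in [0, 1]")
            if name != "hue" and b < a:
                raise ValueError(f"{name} interval is empty")


#: reference windows for the canonical stain colors (configuration, not a
#: published protocol): elastic fibers near-black, collagen pink-red
#: (hue wraps through 0), nuclei hematoxylin purple.
DEFAULT_RANGES: dict[str, HSBRange] = {
    "elastic": HSBRange(hue=(0.0, 1.0), saturation=(0.0, 1.0), brightness=(0.0, 0.25)),
    "collagen": HSBRange(hue=(0.88, 0.05), saturation=(0.30, 1.0), brightness=(0.45, 1.0)),
    "nuclei": HSBRange(hue=(0.62, 0.88), saturation=(0.20, 1.0), brightness=(0.20, 0.92)),
}


@dataclass(frozen=True)
class HistologyImage:
    """RGB raster with µm/px calibration and optional ROI mask.

    ``pixels`` is (H, W, 3) float in [0, 1] or uint8; ``roi`` a boolean
    (H, W) mask restricting all quantification (defaults to the full frame).
    """

    pixels: np.ndarray
    scale_um_per_px: float
    stain: Stain
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB raster")
        if px.dtype == np.uint8:
            px = px.astype(float) / 255.0
        else:
            px = px.astype(float)
            if px.min() < 0 or px.max() > 1 + 1e-9:
                raise ValueError("float pixels must lie in [0, 1]")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale must be positive")
        roi = self.roi
        if roi is not None:
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != px.shape[:2]:
                raise ValueError("roi mask must match the raster shape")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "roi", roi)

    @property
    def roi_mask(self) -> np.ndarray:
        if self.roi is None:
            return np.ones(self.pixels.shape[:2], dtype=bool)
        return self.roi

    @property
    def roi_area_mm2(self) -> float:
        n_px = int(self.roi_mask.sum())
        return n_px * (self.scale_um_per_px / 1000.0) ** 2


@dataclass(frozen=True)
class HistoQuant:
    """Per-specimen histomorphometric record (Table-style row set)."""

    elastic_pct: float | None = None
    collagen_pct: float | None = None
    nuclei_density: float | None = None  # cells / mm^2
    intima_media_pct: float | None = None
    adventitia_pct: float | None = None
    thickness_mm: float | None = None
    radius_mm: float | None = None


def _in_interval(x: np.ndarray, interval: tuple[float, float], circular: bool) -> np.ndarray:
    a, b = interval
    if circular and a > b:
        return (x >= a) | (x <= b)
    return (x >= a) & (x <= b)


def threshold_hsb(image: HistologyImage, rng: HSBRange) -> np.ndarray:
    """Boolean mask of pixels whose HSB triple lies in all three intervals."""
    hsv = color.rgb2hsv(image.pixels)
    mask = (
        _in_interval(hsv[..., 0], rng.hue, circular=True)
        & _in_interval(hsv[..., 1], rng.saturation, circular=False)
        & _in_interval(hsv[..., 2], rng.brightness, circular=False)
    )
    return mask & image.roi_mask


def count_nuclei(
    image: HistologyImage,
    rng: HSBRange | None = None,
    min_area_px2: int = 50,
) -> tuple[int, float]:
    """Count nuclei and return (count, density in cells/mm²).

    Particles are 8-connected components of the thresholded mask with area
    >= ``min_area_px2`` (two disks touching diagonally at a single pixel
    corner merge into one particle under this convention).
    """
    if image.stain != Stain.HE:
        raise ValueError("nuclei are counted on HE-stained images")
    rng = rng or DEFAULT_RANGES["nuclei"]
    mask = threshold_hsb(image, rng)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        count = 0
    else:
        areas = np.bincount(labels.ravel())[1:]
        count = int(np.sum(areas >= min_area_px2))
    area_mm2 = image.roi_area_mm2
    if area_mm2 <= 0:
        raise ValueError("empty ROI: cannot compute density")
    return count, count / area_mm2


def area_fractions(
    image: HistologyImage,
    elastic: HSBRange | None = None,
    collagen: HSBRange | None = None,
) -> tuple[float, float]:
    """(elastic %, collagen %) of the ROI area on a VGE-stained image.

    The black (elastic) test precedes the pink (collagen) test, so a pixel
    matching both windows counts as elastic only.
    """
    if image.stain != Stain.VGE:
        raise ValueError("fiber fractions are measured on VGE-stained images")
    roi = image.roi_mask
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    m_elastic = threshold_hsb(image, elastic or DEFAULT_RANGES["elastic"])
    m_collagen = threshold_hsb(image, collagen or DEFAULT_RANGES["collagen"]) & ~m_elastic
    return (
        100.0 * int(m_elastic.sum()) / n_roi,
        100.0 * int(m_collagen.sum()) / n_roi,
    )


def _polar_radius(polyline: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Radius of a closed polyline about ``center`` sampled at ``angles``."""
    d = polyline - center
    theta = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic padding for interpolation across the -pi/pi seam
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    return np.interp(angles, theta_ext, r_ext)


def layer_percentages(
    boundaries: tuple[np.ndarray, np.ndarray, np.ndarray],
    scale_um_per_px: float = 1.0,
    n_rays: int = 360,
) -> tuple[float, float, float]:
    """Wall-layer shares from three boundary polylines ordered inner→outer.

    ``boundaries`` are (N, 2) arrays of (x, y) vertices in pixels: lumen,
    internal/external elastic boundary, outer edge.  Thicknesses are mean
    radial gaps between consecutive boundaries along matched rays from the
    lumen centroid.  Returns (intima_media %, adventitia %, thickness_mm).
    """
    if len(boundaries) != 3:
        raise ValueError("exactly three boundary polylines are required")
    polys = [np.asarray(b, dtype=float) for b in boundaries]
    for p in polys:
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
            raise ValueError("each boundary needs >= 3 (x, y) vertices")
    center = polys[0].mean(axis=0)
    angles = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
    r1, r2, r3 = (_polar_radius(p, center, angles) for p in polys)
    gap_im = r2 - r1
    gap_ad = r3 - r2
    if np.any(gap_im < -1e-9) or np.any(gap_ad < -1e-9):
        raise ValueError("boundaries cross: annotation is inconsistent")
    t_im = float(gap_im.mean())
    t_ad = float(gap_ad.mean())
    total = t_im + t_ad
    if total <= 1e-12:
        raise ValueError("zero wall thickness between boundaries")
    thickness_mm = total * scale_um_per_px / 1000.0
    return 100.0 * t_im / total, 100.0 * t_ad / total, thickness_mm
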