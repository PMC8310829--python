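"""IBSI-style 2D radiomic features: first-order, shape, GLCM, GLRLM, GLSZM.

Intensities inside the mask are discretized to a fixed number of gray
levels (default 64, ROI min-max) before any texture matrix is built.
Texture families follow the IBSI definitions for 2D images:

- GLCM: symmetric co-occurrence matrices per distance and per angle
  (0, 45, 90, 135 degrees), features averaged over angles;
- GLRLM: run-length matrices over the same four directions, averaged;
- GLSZM: 8-connected zones of equal gray level, single matrix.

All features are finite by construction; degenerate regions (constant
intensity, single pixel pairs) take their documented limit values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu

from .io import Frame
from .segmentation import Mask

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizationConfig",
    "FeatureVector",
    "discretize",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_all",
    "feature_catalogue",
]

# (dy, dx) unit offsets for 0, 45, 90, 135 degrees
_ANGLE_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
DEFAULT_DISTANCES = (1, 2, 4)
SOLID_SUB_PREFIX = "solid_sub::"
_MIN_SUBREGION_PIXELS = 20


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-number gray-level discretization.

    range_mode 'roi_min_max' rescales the observed ROI range onto the bins;
    'fixed' uses the provided (low, high) intensity range instead.
    """

    n_bins: int = 64
    range_mode: str = "roi_min_max"
    fixed_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.range_mode not in ("roi_min_max", "fixed"):
            raise ValueError(f"unknown range_mode {self.range_mode!r}")
        if self.range_mode == "fixed" and self.fixed_range is None:
            raise ValueError("fixed range_mode requires fixed_range")


@dataclass
class FeatureVector:
    """Ordered feature_name -> value map for one (mass, contour-variant) pair."""

    values: dict[str, float]
    panel_id: str = ""
    provenance: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite feature values: {sorted(bad)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def names(self) -> list[str]:
        return list(self.values)


def discretize(
    frame: Frame | np.ndarray, mask: Mask | np.ndarray, cfg: DiscretizationConfig
) -> np.ndarray:
    """Map ROI intensities to integer levels 1..n_bins (0 outside the mask).

    level = 1 + floor(n_bins * (I - min) / (max - min)), clamped to n_bins
    at the maximum; a constant ROI maps wholly to level 1.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if m.sum() == 0:
        raise ValueError("empty mask")
    vals = pixels[m].astype(float)
    if cfg.range_mode == "fixed":
        lo, hi = cfg.fixed_range
    else:
        lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(pixels.shape, dtype=np.int32)
    if hi <= lo:
        levels[m] = 1
        return levels
    scaled = 1 + np.floor(cfg.n_bins * (pixels[m].astype(float) - lo) / (hi - lo))
    levels[m] = np.clip(scaled, 1, cfg.n_bins).astype(np.int32)
    return levels


# ---------------------------------------------------------------------------
# first order


def first_order_features(
    frame: Frame | np.ndarray, mask: Mask | np.ndarray, levels: np.ndarray
) -> dict[str, float]:
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    x = pixels[m].astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    centered = x - mean
    skew = float(np.mean(centered**3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean(centered**4) / sd**4 - 3.0) if sd > 0 else 0.0
    lv = levels[m]
    p = np.bincount(lv)[1:] / n
    p = p[p > 0]
    return {
        "fo_mean": mean,
        "fo_variance": var,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": float(np.sum(x**2)),
        "fo_entropy": float(-np.sum(p * np.log2(p))),
        "fo_p10": float(np.percentile(x, 10)),
        "fo_p90": float(np.percentile(x, 90)),
        "fo_iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "fo_range": float(x.max() - x.min()),
        "fo_mad": float(np.mean(np.abs(centered))),
        "fo_rms": float(np.sqrt(np.mean(x**2))),
        "fo_uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape


def shape_features(
    mask: Mask | np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)
) -> dict[str, float]:
    """Morphometry of the mask in physical units.

    Area is pixel count times the pixel area. The perimeter uses the Crofton
    estimator (4 directions), which is asymptotically unbiased for smooth
    boundaries where a raw iso-contour staircase overestimates length by
    several percent (a digital disk then keeps circularity near 1). Ellipse
    axes, Feret diameter, perimeter and solidity assume isotropic spacing
    (the mean of row/col spacing is used if it is not).
    """
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    sp = float(np.mean(spacing))
    area = float(m.sum()) * spacing[0] * spacing[1]
    perimeter = float(measure.perimeter_crofton(m, directions=4)) * sp

    props = measure.regionprops(m.astype(np.uint8))[0]
    major = float(props.axis_major_length) * sp
    minor = float(props.axis_minor_length) * sp
    circ = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
    return {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_equivalent_diameter": float(2.0 * np.sqrt(area / np.pi)),
        "shape_major_axis": major,
        "shape_minor_axis": minor,
        "shape_eccentricity": float(props.eccentricity),
        "shape_circularity": circ,
        "shape_solidity": float(m.sum()) / convex_hull_area(m),
        "shape_feret_max": float(props.feret_diameter_max) * sp,
    }


def convex_hull_area(m: np.ndarray) -> float:
    """Geometric area (px^2) of the convex hull of the mask's pixel squares.

    Each foreground pixel contributes its four corners; the hull of a b x b
    square of pixels therefore has area exactly b**2, consistent with the
    pixel-counting area.
    """
    pts = np.argwhere(m).astype(float)
    # boundary pixels suffice for the hull
    eroded = ndimage.binary_erosion(m)
    boundary = np.argwhere(m & ~eroded).astype(float)
    base = boundary if len(boundary) >= 3 else pts
    offsets = np.array([(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)])
    corners = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    return float(ConvexHull(corners).volume)


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(
    levels: np.ndarray, m: np.ndarray, offset: tuple[int, int], n_bins: int
) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one (dy, dx) offset."""
    dy, dx = offset
    h, w = levels.shape
    ys, xs = np.nonzero(m)
    y2, x2 = ys + dy, xs + dx
    ok = (y2 >= 0) & (y2 < h) & (x2 >= 0) & (x2 < w)
    ys, xs, y2, x2 = ys[ok], xs[ok], y2[ok], x2[ok]
    ok = m[y2, x2]
    if not np.any(ok):
        return None
    a = levels[ys[ok], xs[ok]] - 1
    b = levels[y2[ok], x2[ok]] - 1
    counts = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    )
    counts = counts + counts.T  # symmetric
    return counts / counts.sum()


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _index_grids(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GRID_CACHE:
        i = np.arange(1, n + 1, dtype=float)
        _GRID_CACHE[n] = np.meshgrid(i, i, indexing="ij")
    return _GRID_CACHE[n]


def _glcm_scalar_features(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = _index_grids(n)
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma = float(np.sqrt(np.sum((i - mu) ** 2 * px)))
    diff = np.abs(ii - jj)
    nz = p[p > 0]
    if sigma > 0:
        corr = float(np.sum(p * (ii - mu) * (jj - mu)) / sigma**2)
    else:
        corr = 1.0  # degenerate single-level ROI
    return {
        "contrast": float(np.sum(p * (ii - jj) ** 2)),
        "dissimilarity": float(np.sum(p * diff)),
        "homogeneity": float(np.sum(p / (1.0 + diff))),
        "asm": float(np.sum(p**2)),
        "correlation": corr,
        "joint_entropy": float(-np.sum(nz * np.log2(nz))),
        "cluster_shade": float(np.sum(p * (ii + jj - 2.0 * mu) ** 3)),
        "cluster_prominence": float(np.sum(p * (ii + jj - 2.0 * mu) ** 4)),
    }


def glcm_features(
    levels: np.ndarray,
    mask: Mask | np.ndarray,
    distances: Iterable[int] = DEFAULT_DISTANCES,
    n_bins: int | None = None,
) -> dict[str, float]:
    """Angle-averaged co-occurrence features per distance.

    For a distance at which no within-mask pixel pair exists in any
    direction the features are omitted with a warning.
    """
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    nb = n_bins or int(levels.max())
    out: dict[str, float] = {}
    for d in distances:
        per_angle: list[dict[str, float]] = []
        for dy, dx in _ANGLE_OFFSETS:
            p = _glcm_matrix(levels, m, (dy * d, dx * d), nb)
            if p is not None:
                per_angle.append(_glcm_scalar_features(p))
        if not per_angle:
            logger.warning("no within-mask pixel pairs at distance %d; omitted", d)
            continue
        for name in per_angle[0]:
            out[f"glcm_d{d}_{name}"] = float(np.mean([f[name] for f in per_angle]))
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _lines_for_direction(levels_masked: np.ndarray, direction: tuple[int, int]):
    """Flatten the image into zero-separated scan lines along a direction."""
    arr = levels_masked
    dy, dx = direction
    if (dy, dx) == (0, 1):
        lines = arr
    elif (dy, dx) == (1, 0):
        lines = arr.T
    else:
        h, w = arr.shape
        sheared = np.zeros((h, w + h), dtype=arr.dtype)
        for i in range(h):
            if dx == 1:  # down-right diagonals
                sheared[i, h - 1 - i : h - 1 - i + w] = arr[i]
            else:  # down-left diagonals
                sheared[i, i : i + w] = arr[i]
        lines = sheared.T
    sep = np.zeros((lines.shape[0], 1), dtype=arr.dtype)
    return np.hstack([lines, sep]).ravel()


def _run_lengths(flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of equal nonzero values in a zero-separated sequence."""
    if flat.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    change = np.nonzero(np.diff(flat) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    vals = flat[starts]
    keep = vals > 0
    return vals[keep], (ends - starts)[keep]


def _glrlm_scalar_features(
    grays: np.ndarray, lengths: np.ndarray, n_pixels: int
) -> dict[str, float]:
    nr = len(grays)
    g = grays.astype(float)
    l = lengths.astype(float)
    # non-uniformities need marginal sums over equal gray / equal length
    g_marg = np.bincount(grays)[1:].astype(float)
    l_marg = np.bincount(lengths)[1:].astype(float)
    return {
        "sre": float(np.sum(1.0 / l**2) / nr),
        "lre": float(np.sum(l**2) / nr),
        "gln": float(np.sum(g_marg**2) / nr),
        "rln": float(np.sum(l_marg**2) / nr),
        "run_percentage": float(nr / n_pixels),
        "lglre": float(np.sum(1.0 / g**2) / nr),
        "hglre": float(np.sum(g**2) / nr),
    }


_RUN_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glrlm_features(levels: np.ndarray, mask: Mask | np.ndarray) -> dict[str, float]:
    """Run-length features averaged over the four principal directions."""
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    masked = np.where(m, levels, 0)
    n_pixels = int(m.sum())
    per_dir = []
    for direction in _RUN_DIRECTIONS:
        grays, lengths = _run_lengths(_lines_for_direction(masked, direction))
        if len(grays) == 0:
            continue
        per_dir.append(_glrlm_scalar_features(grays, lengths, n_pixels))
    out: dict[str, float] = {}
    if not per_dir:
        logger.warning("no runs found in mask; GLRLM features omitted")
        return out
    for name in per_dir[0]:
        out[f"glrlm_{name}"] = float(np.mean([f[name] for f in per_dir]))
    return out


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(levels: np.ndarray, mask: Mask | np.ndarray) -> dict[str, float]:
    """Size-zone features from 8-connected zones of equal gray level."""
    m = mask.array if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    masked = np.where(m, levels, 0)
    n_pixels = int(m.sum())
    structure = np.ones((3, 3), dtype=int)
    zone_grays: list[int] = []
    zone_sizes: list[int] = []
    for g in np.unique(masked[masked > 0]):
        labeled, n = ndimage.label(masked == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zone_grays.extend([int(g)] * n)
        zone_sizes.extend(int(s) for s in sizes)
    nz = len(zone_sizes)
    if nz == 0:
        logger.warning("no zones found in mask; GLSZM features omitted")
        return {}
    g = np.asarray(zone_grays, dtype=float)
    s = np.asarray(zone_sizes, dtype=float)
    g_marg = np.bincount(zone_grays)[1:].astype(float)
    s_marg = np.bincount(zone_sizes)[1:].astype(float)
    return {
        "glszm_sze": float(np.sum(1.0 / s**2) / nz),
        "glszm_lze": float(np.sum(s**2) / nz),
        "glszm_szn": float(np.sum(s_marg**2) / nz),
        "glszm_gln": float(np.sum(g_marg**2) / nz),
        "glszm_zone_percentage": float(nz / n_pixels),
    }


# ---------------------------------------------------------------------------
# full extraction


def extract_all(
    frame: Frame,
    mask: Mask,
    mass_type: str,
    disc_cfg: DiscretizationConfig | None = None,
    distances: Iterable[int] = DEFAULT_DISTANCES,
    provenance: tuple[str, int] = ("", 0),
) -> FeatureVector:
    """Concatenate first-order, shape and texture fragments for one mask.

    The candidate catalogue is identical for the three mass types; for mixed
    masses every feature is additionally computed on the solid subregion
    (Otsu-thresholded within the contour) under the ``solid_sub::`` prefix.
    Panels only diverge later, at stability selection.
    """
    disc_cfg = disc_cfg or DiscretizationConfig()
    values = _extract_fragments(frame, mask.array, disc_cfg, distances)
    if mass_type == "mixed":
        sub = _solid_subregion(frame, mask.array)
        for name, v in _extract_fragments(frame, sub, disc_cfg, distances).items():
            values[SOLID_SUB_PREFIX + name] = v
    return FeatureVector(values=values, panel_id=mass_type, provenance=provenance)


def _extract_fragments(
    frame: Frame,
    m: np.ndarray,
    disc_cfg: DiscretizationConfig,
    distances: Iterable[int],
) -> dict[str, float]:
    # texture matrices only see within-mask pairs, so everything can be
    # computed on the mask bounding box (one-pixel margin for the contour)
    ys, xs = np.nonzero(m)
    y0, y1 = max(ys.min() - 1, 0), min(ys.max() + 2, m.shape[0])
    x0, x1 = max(xs.min() - 1, 0), min(xs.max() + 2, m.shape[1])
    sub_pixels = frame.pixels[y0:y1, x0:x1]
    sub_m = m[y0:y1, x0:x1]

    levels = discretize(sub_pixels, sub_m, disc_cfg)
    values: dict[str, float] = {}
    values.update(first_order_features(sub_pixels, sub_m, levels))
    values.update(shape_features(sub_m, frame.pixel_spacing))
    values.update(glcm_features(levels, sub_m, distances, n_bins=disc_cfg.n_bins))
    values.update(glrlm_features(levels, sub_m))
    values.update(glszm_features(levels, sub_m))
    return values


def _solid_subregion(frame: Frame, m: np.ndarray) -> np.ndarray:
    """Brighter-than-Otsu pixels within the contour; falls back to the full
    mask when the subregion is too small for texture matrices."""
    vals = frame.pixels[m].astype(float)
    if vals.max() <= vals.min():
        return m
    thr = threshold_otsu(vals)
    sub = m & (frame.pixels > thr)
    if sub.sum() < _MIN_SUBREGION_PIXELS:
        return m
    return sub


def feature_catalogue(
    mass_type: str = "solid", distances: Iterable[int] = DEFAULT_DISTANCES
) -> list[str]:
    """Names of every candidate feature for a mass type, in extraction order."""
    base: list[str] = []
    base += [
        "fo_mean", "fo_variance", "fo_skewness", "fo_kurtosis", "fo_energy",
        "fo_entropy", "fo_p10", "fo_p90", "fo_iqr", "fo_range", "fo_mad",
        "fo_rms", "fo_uniformity",
    ]
    base += [
        "shape_area", "shape_perimeter", "shape_equivalent_diameter",
        "shape_major_axis", "shape_minor_axis", "shape_eccentricity",
        "shape_circularity", "shape_solidity", "shape_feret_max",
    ]
    glcm_names = [
        "contrast", "dissimilarity", "homogeneity", "asm", "correlation",
        "joint_entropy", "cluster_shade", "cluster_prominence",
    ]
    for d in distances:
        base += [f"glcm_d{d}_{n}" for n in glcm_names]
    base += [f"glrlm_{n}" for n in ("sre", "lre", "gln", "rln", "run_percentage", "lglre", "hglre")]
    base += [f"glszm_{n}" for n in ("sze", "lze", "szn", "gln", "zone_percentage")]
    if mass_type == "mixed":
        base = base + [SOLID_SUB_PREFIX + n for n in base]
    return base
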