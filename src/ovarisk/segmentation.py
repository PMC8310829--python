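"""Contour rasterization and random contour manipulation.

The manual mass contour is rasterized with an even-odd pixel-center rule
(a pixel belongs to the mask iff its center lies inside the polygon, with
the half-open convention on shared boundaries), then randomly manipulated
to emulate the small tracing differences between operators: each variant
displaces the contour radially from its centroid by a smooth random field
built from a handful of low-order Fourier harmonics in vertex angle. The
downstream feature-stability selection relies on these variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

MIN_MASK_PIXELS = 50

__all__ = [
    "Mask",
    "PerturbationConfig",
    "MaskTooSmallError",
    "rasterize",
    "perturb_contour",
    "polygon_mask",
]


class MaskTooSmallError(ValueError):
    """Polygon rasterizes to fewer foreground pixels than features need."""


@dataclass
class Mask:
    """Binary region congruent with its frame; single connected component."""

    array: np.ndarray

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=bool)
        if self.array.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def pixel_count(self) -> int:
        return int(self.array.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape


@dataclass(frozen=True)
class PerturbationConfig:
    """Controls the random contour manipulations.

    amplitude_frac is the peak radial displacement as a fraction of the
    contour's equivalent radius; smoothness is the number of low-order
    harmonics in the displacement field (fewer harmonics = smoother).
    """

    n_variants: int = 20
    amplitude_frac: float = 0.05
    smoothness: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.amplitude_frac <= 0.15:
            raise ValueError("amplitude_frac must lie in [0, 0.15]")
        if self.smoothness < 1:
            raise ValueError("smoothness must be >= 1")


def polygon_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd pixel-center rasterization of a polygon onto a raster grid.

    A pixel center (x, y) is inside iff a ray cast toward +x crosses the
    polygon boundary an odd number of times, counting an edge crossing when
    ``y1 <= y < y2`` (half-open), which makes an axis-aligned [a, b) box
    contain exactly (b-a)**2 pixel centers.
    """
    contour = np.asarray(contour, dtype=float)
    h, w = shape
    x0 = max(int(np.floor(contour[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(contour[:, 0].max())) + 1, w - 1)
    y0 = max(int(np.floor(contour[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(contour[:, 1].max())) + 1, h - 1)
    if x1 < x0 or y1 < y0:
        return np.zeros(shape, dtype=bool)
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    inside = np.zeros(X.shape, dtype=bool)
    n = len(contour)
    for i in range(n):
        ax, ay = contour[i]
        bx, by = contour[(i + 1) % n]
        if ay == by:
            continue  # horizontal edges never cross the half-open band
        crosses = (ay > Y) != (by > Y)
        x_int = ax + (Y - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (x_int > X)
    out = np.zeros(shape, dtype=bool)
    out[y0 : y1 + 1, x0 : x1 + 1] = inside
    return out


def rasterize(contour: np.ndarray, frame_shape: tuple[int, int]) -> Mask:
    """Rasterize a simple closed polygon; keep the largest connected component.

    Raises MaskTooSmallError below the 50-pixel floor required for texture
    feature extraction.
    """
    raw = polygon_mask(contour, frame_shape)
    if raw.sum() < MIN_MASK_PIXELS:
        raise MaskTooSmallError(
            f"polygon rasterizes to {int(raw.sum())} pixels (< {MIN_MASK_PIXELS})"
        )
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
        if raw.sum() < MIN_MASK_PIXELS:
            raise MaskTooSmallError(
                f"largest component has {int(raw.sum())} pixels (< {MIN_MASK_PIXELS})"
            )
    return Mask(raw)


def equivalent_radius(contour: np.ndarray) -> float:
    """Radius of the circle with the polygon's (shoelace) area."""
    return float(np.sqrt(abs(_shoelace_area(contour)) / np.pi))


def _shoelace_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perturb_contour(
    contour: np.ndarray,
    cfg: PerturbationConfig,
    frame_shape: tuple[int, int] | None = None,
) -> list[np.ndarray]:
    """Generate random smooth manipulations of a contour.

    Each variant displaces every vertex radially from the contour centroid by
    ``d(theta) = A * sum_h a_h cos(h*theta + phi_h)``, the sum running over
    the first ``cfg.smoothness`` harmonics with random amplitudes and phases,
    normalized so the peak displacement is at most ``amplitude_frac`` times
    the equivalent radius. With ``amplitude_frac = 0`` the variants equal
    the input exactly. Variants escaping the frame are clipped to bounds
    with a warning.
    """
    contour = np.asarray(contour, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    centroid = contour.mean(axis=0)
    rel = contour - centroid
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    radius = np.hypot(rel[:, 0], rel[:, 1])
    r_eq = equivalent_radius(contour)

    variants: list[np.ndarray] = []
    for _ in range(cfg.n_variants):
        harmonics = np.arange(1, cfg.smoothness + 1)
        amps = rng.uniform(0.0, 1.0, size=cfg.smoothness)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.smoothness)
        # peak-displacement magnitude drawn anew per variant
        peak = rng.uniform(0.3, 1.0) * cfg.amplitude_frac * r_eq
        if cfg.amplitude_frac == 0.0:
            variants.append(contour.copy())
            continue
        field = np.sum(
            amps[:, None] * np.cos(harmonics[:, None] * theta[None, :] + phases[:, None]),
            axis=0,
        )
        max_abs = np.max(np.abs(field))
        if max_abs > 0:
            field = field / max_abs * peak
        new_r = np.maximum(radius + field, 0.1 * radius)
        variant = centroid + np.column_stack(
            (new_r * np.cos(theta), new_r * np.sin(theta))
        )
        if frame_shape is not None:
            h, w = frame_shape
            clipped = np.column_stack(
                (np.clip(variant[:, 0], 0, w - 1), np.clip(variant[:, 1], 0, h - 1))
            )
            if not np.array_equal(clipped, variant):
                logger.warning("perturbed contour left frame bounds; clipped")
                variant = clipped
        variants.append(variant)
    return variants
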