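"""Synthetic ultrasound-like phantoms of adnexal masses.

Real transvaginal-ultrasound cohorts for this problem are not publicly
deposited, so every pipeline stage is exercised on speckled phantom frames
that reproduce the statistical structure the decision support system
relies on:

- background: a smooth tissue-intensity field multiplied by Rayleigh
  speckle (unit mean), lightly smoothed to mimic the lateral correlation
  of B-mode texture;
- the mass is an ellipse-derived region: cystic = hypoechoic interior,
  solid = hyperechoic textured interior, mixed = cystic region with one
  or more solid mural nodules;
- malignancy raises boundary irregularity (radial harmonic noise on the
  contour) and interior heterogeneity (texture-contrast parameter);
- an optional posterior acoustic shadow attenuates a trapezoidal band
  below the mass;
- serum CA-125 is log-normal with class-conditional medians (benign 25,
  malignant 250 pre- / 150 post-menopause U/mL) that straddle the
  decision thresholds of 200 / 71 U/mL.

This is a statistical phantom, not a physical B-mode simulation: there is
no scatterer field or point-spread-function convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    CaseRecord,
    ClinicalRecord,
    Frame,
    MassAnnotation,
    write_contour_csv,
    write_frame_dicom,
    write_manifest,
)
from .segmentation import polygon_mask

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "GeneratorParams",
    "SizingError",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "sample_ca125",
    "contour_radial_variance",
]


class SizingError(ValueError):
    """Requested mass does not fit in the frame."""


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable distributions of the phantom generator (all intensities 0-255).

    Defaults are calibrated so the class-conditional CA-125 medians straddle
    the menopause-corrected decision thresholds and the malignant/benign
    contrast in boundary irregularity and texture heterogeneity is of the
    size a radiomic classifier is expected to exploit.
    """

    background_level: float = 110.0
    background_gradient: float = 25.0
    speckle_smoothing_sigma: float = 0.8
    cystic_level: float = 32.0
    solid_level: float = 175.0
    # uniform ranges for the peak relative radial contour noise
    irregularity_benign: tuple[float, float] = (0.01, 0.05)
    irregularity_malignant: tuple[float, float] = (0.08, 0.15)
    # multiplier of the smooth interior heterogeneity field
    heterogeneity_benign: float = 0.06
    heterogeneity_malignant: float = 0.30
    shadow_attenuation: float = 0.35
    # CA-125 log-normal medians (U/mL) and log-scale sigmas
    ca125_median_benign: float = 25.0
    ca125_median_malignant_pre: float = 250.0
    ca125_median_malignant_post: float = 150.0
    ca125_sigma_benign: float = 1.0
    ca125_sigma_malignant: float = 0.9
    # cohort-level assignment probabilities
    p_shadow_benign: float = 0.30
    p_shadow_malignant: float = 0.05
    p_postmenopausal: float = 0.60


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines one phantom case; seed fixes all sampling."""

    mass_type: str
    malignant: bool
    shadow: bool
    menopausal: str
    seed: int
    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: float = 0.2  # mm per pixel, isotropic
    params: GeneratorParams = field(default_factory=GeneratorParams)

    def __post_init__(self) -> None:
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64x64")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.mass_type not in ("solid", "cystic", "mixed"):
            raise ValueError(f"unknown mass_type {self.mass_type!r}")
        if self.menopausal not in ("pre", "post"):
            raise ValueError(f"unknown menopausal status {self.menopausal!r}")


@dataclass
class PhantomCase:
    frame: Frame
    annotation: MassAnnotation
    clinical: ClinicalRecord
    label: str | None  # "benign" / "malignant"; None at inference time
    case_id: str = ""


def sample_ca125(
    malignant: bool, menopausal: str, rng: np.random.Generator,
    params: GeneratorParams | None = None,
) -> float:
    """Draw a serum CA-125 level (U/mL) from the class-conditional log-normal."""
    p = params or GeneratorParams()
    if malignant:
        median = (
            p.ca125_median_malignant_pre
            if menopausal == "pre"
            else p.ca125_median_malignant_post
        )
        sigma = p.ca125_sigma_malignant
    else:
        median = p.ca125_median_benign
        sigma = p.ca125_sigma_benign
    return float(rng.lognormal(mean=np.log(median), sigma=sigma))


def contour_radial_variance(contour: np.ndarray) -> float:
    """Boundary-irregularity statistic: variance of the radial profile after
    removing its ellipse content, normalized by the squared mean radius.

    The raw variance of centroid distances is dominated by elongation, so
    the mean and the first two Fourier harmonics of r(theta) (centroid
    offset and ellipse) are removed first; what is left is scale-free
    boundary roughness. Vertices are assumed roughly uniform in angle.
    """
    contour = np.asarray(contour, dtype=float)
    rel = contour - contour.mean(axis=0)
    r = np.hypot(rel[:, 0], rel[:, 1])
    spectrum = np.fft.rfft(r)
    spectrum[:3] = 0.0
    residual = np.fft.irfft(spectrum, n=len(r))
    return float(np.var(residual) / np.mean(r) ** 2)


def _speckle(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Unit-mean Rayleigh multiplicative speckle, lightly smoothed."""
    raw = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
    if sigma > 0:
        raw = ndimage.gaussian_filter(raw, sigma)
    return raw / raw.mean()


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 3.0) -> np.ndarray:
    """Zero-mean unit-std band-limited field for interior heterogeneity."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _mass_contour(
    rng: np.random.Generator, spec: PhantomSpec, n_vertices: int = 180
) -> np.ndarray:
    h, w = spec.image_size
    p = spec.params
    cy = h * 0.45 + rng.uniform(-0.04, 0.04) * h
    cx = w * 0.5 + rng.uniform(-0.05, 0.05) * w
    base = 0.16 * min(h, w)
    a = base * rng.uniform(0.9, 1.45)  # semi-axes in pixels
    b = a * rng.uniform(0.65, 1.0)
    tilt = rng.uniform(0.0, np.pi)
    lo, hi = p.irregularity_malignant if spec.malignant else p.irregularity_benign
    amp = rng.uniform(lo, hi)

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # radius of the tilted ellipse in polar form
    ct, st = np.cos(theta - tilt), np.sin(theta - tilt)
    r = (a * b) / np.sqrt((b * ct) ** 2 + (a * st) ** 2)
    harmonics = np.arange(2, 9)
    amps = rng.uniform(0.2, 1.0, size=harmonics.size)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=harmonics.size)
    fieldv = np.sum(
        amps[:, None] * np.cos(harmonics[:, None] * theta[None, :] + phases[:, None]),
        axis=0,
    )
    fieldv = fieldv / np.max(np.abs(fieldv)) * amp
    r = r * (1.0 + fieldv)
    contour = np.column_stack((cx + r * np.cos(theta), cy + r * np.sin(theta)))
    margin = 2.0
    if (
        contour[:, 0].min() < margin
        or contour[:, 1].min() < margin
        or contour[:, 0].max() > w - 1 - margin
        or contour[:, 1].max() > h - 1 - margin
    ):
        raise SizingError("mass does not fit in the frame; enlarge image_size")
    return contour


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case; the PhantomSpec seed fully determines the output."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    p = spec.params

    yy = np.arange(h)[:, None] / max(h - 1, 1)
    background = p.background_level + p.background_gradient * yy * np.ones((h, w))
    contour = _mass_contour(rng, spec)
    mask = polygon_mask(contour, (h, w))

    het = _smooth_field((h, w), rng)
    contrast = p.heterogeneity_malignant if spec.malignant else p.heterogeneity_benign

    tissue = background.copy()
    if spec.mass_type == "cystic":
        interior = p.cystic_level * (1.0 + contrast * het)
        tissue[mask] = interior[mask]
    elif spec.mass_type == "solid":
        interior = p.solid_level * (1.0 + contrast * het)
        tissue[mask] = interior[mask]
    else:  # mixed: cystic region with solid mural nodules
        interior = p.cystic_level * (1.0 + contrast * het)
        tissue[mask] = interior[mask]
        nodule_mask = _mural_nodules(rng, contour, mask, spec)
        solid = p.solid_level * (1.0 + contrast * het)
        tissue[nodule_mask] = solid[nodule_mask]

    image = np.clip(tissue, 1.0, None) * _speckle((h, w), rng, p.speckle_smoothing_sigma)

    if spec.shadow:
        image *= _shadow_field(contour, (h, w), p.shadow_attenuation)

    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    frame = Frame(
        pixels=pixels,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        case_id=f"phantom-{spec.seed}",
    )
    annotation = MassAnnotation(
        mass_type=spec.mass_type, contour=contour, shadow_present=spec.shadow
    )
    clinical = ClinicalRecord(
        ca125=sample_ca125(spec.malignant, spec.menopausal, rng, p),
        menopausal=spec.menopausal,
    )
    return PhantomCase(
        frame=frame,
        annotation=annotation,
        clinical=clinical,
        label="malignant" if spec.malignant else "benign",
        case_id=frame.case_id,
    )


def _mural_nodules(
    rng: np.random.Generator,
    contour: np.ndarray,
    mask: np.ndarray,
    spec: PhantomSpec,
) -> np.ndarray:
    """One to three solid nodules seated on the inner cyst wall."""
    h, w = spec.image_size
    centroid = contour.mean(axis=0)
    n_nodules = int(rng.integers(1, 4))
    nodule = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_nodules):
        v = contour[rng.integers(0, len(contour))]
        # place the nodule center between the wall and the centroid
        t = rng.uniform(0.25, 0.45)
        cx, cy = v + t * (centroid - v)
        rad = rng.uniform(0.12, 0.22) * np.hypot(*(v - centroid))
        rad = max(rad, 3.0)
        nodule |= (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    return nodule & mask


def _shadow_field(
    contour: np.ndarray, shape: tuple[int, int], attenuation: float
) -> np.ndarray:
    """Trapezoidal attenuation band below the mass (narrowing slightly
    with depth, as posterior shadows do)."""
    h, w = shape
    x_lo, x_hi = contour[:, 0].min(), contour[:, 0].max()
    y_bottom = contour[:, 1].max()
    field = np.ones((h, w))
    center = 0.5 * (x_lo + x_hi)
    half = 0.5 * (x_hi - x_lo)
    for y in range(int(np.ceil(y_bottom)), h):
        depth = (y - y_bottom) / max(h - y_bottom, 1.0)
        hw = half * (1.0 - 0.3 * depth)
        lo, hi = int(np.floor(center - hw)), int(np.ceil(center + hw))
        field[y, max(lo, 0) : min(hi + 1, w)] = attenuation
    return field


def generate_cohort(
    n: int,
    prevalence: float,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
    params: GeneratorParams | None = None,
) -> list[PhantomCase]:
    """Generate a cohort with exact malignant count round(n * prevalence)
    and mass-type counts apportioned by ``mix`` (largest remainder)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    mix = mix or {"solid": 0.35, "cystic": 0.30, "mixed": 0.35}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    params = params or GeneratorParams()

    n_malignant = int(np.floor(n * prevalence + 0.5))
    labels = [True] * n_malignant + [False] * (n - n_malignant)
    types: list[str] = []
    exact = {t: n * frac for t, frac in sorted(mix.items())}
    floors = {t: int(np.floor(v)) for t, v in exact.items()}
    leftover = n - sum(floors.values())
    by_remainder = sorted(exact, key=lambda t: (exact[t] - floors[t], t), reverse=True)
    for t in sorted(mix):
        types += [t] * floors[t]
    for t in by_remainder[:leftover]:
        types.append(t)

    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    rng.shuffle(types)

    cases: list[PhantomCase] = []
    for i, (malignant, mass_type) in enumerate(zip(labels, types)):
        p_shadow = params.p_shadow_malignant if malignant else params.p_shadow_benign
        shadow = bool(rng.random() < p_shadow)
        menopausal = "post" if rng.random() < params.p_postmenopausal else "pre"
        case_seed = int(
            np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31)
        )
        spec = PhantomSpec(
            mass_type=mass_type,
            malignant=malignant,
            shadow=shadow,
            menopausal=menopausal,
            seed=case_seed,
            image_size=image_size,
            params=params,
        )
        case = generate_phantom(spec)
        case.case_id = f"case{i:04d}"
        case.frame.case_id = case.case_id
        cases.append(case)
    return cases


def write_cohort(cases: list[PhantomCase], outdir: str | Path, png: bool = False) -> Path:
    """Write frames (DICOM), contours (CSV) and the cohort manifest (CSV)."""
    from .io import write_frame_png

    outdir = Path(outdir)
    records = []
    for case in cases:
        image_rel = f"frames/{case.case_id}.dcm"
        contour_rel = f"contours/{case.case_id}.csv"
        write_frame_dicom(case.frame, outdir / image_rel, uid_entropy=case.case_id)
        if png:
            write_frame_png(case.frame, outdir / f"frames/{case.case_id}.png")
        write_contour_csv(case.annotation.contour, outdir / contour_rel)
        records.append(
            CaseRecord(
                case_id=case.case_id,
                image_path=image_rel,
                contour_path=contour_rel,
                annotation=case.annotation,
                clinical=case.clinical,
                label=case.label,
            )
        )
    return write_manifest(records, outdir / "manifest.csv")
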