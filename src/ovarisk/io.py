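"""Readers and writers for frames (DICOM/PNG), contours (CSV) and manifests.

Conventions used throughout the package:

- pixel coordinates are 0-based and pixel-centered, with x = column and
  y = row; contour vertices are floating point;
- RGB images are collapsed to luminance with the ITU-R BT.601 weights;
- a frame without pixel-spacing metadata gets (1.0, 1.0) mm with a logged
  warning, so shape features degrade gracefully to pixel units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

logger = logging.getLogger(__name__)

MASS_TYPES = ("solid", "cystic", "mixed")
MENOPAUSAL = ("pre", "post")

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = [
    "case_id",
    "image_path",
    "contour_path",
    "mass_type",
    "shadow",
    "ca125",
    "menopausal",
    "label",
]


class UnsupportedInputError(ValueError):
    """Raised for inputs outside the single-frame 2D grayscale contract."""


@dataclass
class Frame:
    """One 2D grayscale ultrasound frame with physical pixel spacing (mm)."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (row mm, col mm)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(f"frame must be 2D and >= 2x2, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("frame intensities must be finite")
        if np.any(self.pixels.astype(float) < 0):
            raise ValueError("frame intensities must be non-negative")
        if min(self.pixel_spacing) <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MassAnnotation:
    """Examiner input: echotexture class, closed contour, shadow flag."""

    mass_type: str
    contour: np.ndarray  # (n, 2) float array of (x, y) vertices
    shadow_present: bool

    def __post_init__(self) -> None:
        if self.mass_type not in MASS_TYPES:
            raise ValueError(
                f"mass_type must be one of {MASS_TYPES}, got {self.mass_type!r}"
            )
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 or len(self.contour) < 3:
            raise ValueError("contour must be an (n>=3, 2) array of (x, y) vertices")
        self.shadow_present = bool(self.shadow_present)


@dataclass
class ClinicalRecord:
    """Serum CA-125 (U/mL) and menopausal status."""

    ca125: float
    menopausal: str

    def __post_init__(self) -> None:
        self.ca125 = float(self.ca125)
        if not np.isfinite(self.ca125) or self.ca125 < 0:
            raise ValueError(f"ca125 must be finite and >= 0, got {self.ca125}")
        if self.menopausal not in MENOPAUSAL:
            raise ValueError(
                f"menopausal must be one of {MENOPAUSAL}, got {self.menopausal!r}"
            )


@dataclass
class CaseRecord:
    """One manifest row: frame reference plus annotation and clinical data."""

    case_id: str
    image_path: str
    contour_path: str
    annotation: MassAnnotation
    clinical: ClinicalRecord
    label: str | None = None  # "benign" / "malignant", absent at inference
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frames


def read_frame(path: str | Path, case_id: str | None = None) -> Frame:
    """Read a single-frame grayscale image from DICOM or PNG.

    RGB content is converted to BT.601 luminance. Pixel spacing is taken
    from the DICOM PixelSpacing (or ImagerPixelSpacing) tag; PNG carries
    no physical spacing, so it defaults to 1.0 mm with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"frame file not found: {path}")
    if path.suffix.lower() in (".dcm", ".dicom") or _looks_like_dicom(path):
        return _read_dicom_frame(path, case_id)
    return _read_png_frame(path, case_id)


def _looks_like_dicom(path: Path) -> bool:
    with open(path, "rb") as fh:
        fh.seek(128)
        return fh.read(4) == b"DICM"


def _read_dicom_frame(path: Path, case_id: str | None) -> Frame:
    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise UnsupportedInputError(f"{path}: multi-frame object ({n_frames} frames)")
    arr = ds.pixel_array
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = _to_luminance(arr)
    elif arr.ndim != 2:
        raise UnsupportedInputError(f"{path}: unsupported pixel array shape {arr.shape}")
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        logger.warning("%s: no pixel-spacing tag; defaulting to 1.0 mm", path)
        spacing = (1.0, 1.0)
    spacing = (float(spacing[0]), float(spacing[1]))
    cid = case_id or str(getattr(ds, "PatientID", "")) or path.stem
    return Frame(pixels=arr, pixel_spacing=spacing, case_id=cid)


def _read_png_frame(path: Path, case_id: str | None) -> Frame:
    try:
        img = Image.open(path)
        arr = np.asarray(img)
    except Exception as exc:  # noqa: BLE001 - surfaced as I/O error
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = _to_luminance(arr[..., :3])
    logger.warning("%s: PNG has no physical spacing; defaulting to 1.0 mm", path)
    return Frame(pixels=arr, pixel_spacing=(1.0, 1.0), case_id=case_id or path.stem)


def _to_luminance(rgb: np.ndarray) -> np.ndarray:
    luma = rgb.astype(float) @ _LUMA
    return np.rint(luma).astype(rgb.dtype)


def write_frame_dicom(
    frame: Frame, path: str | Path, *, uid_entropy: str | None = None
) -> Path:
    """Write a frame as single-frame grayscale secondary-capture DICOM.

    UIDs are derived deterministically from the case id (or ``uid_entropy``),
    so re-writing the same frame is byte-identical.
    """
    path = Path(path)
    arr = np.ascontiguousarray(frame.pixels)
    if arr.dtype != np.uint8:
        if arr.max() > 255 or np.any(arr != np.rint(arr)):
            raise ValueError("DICOM export expects 8-bit integer intensities")
        arr = arr.astype(np.uint8)

    entropy = [uid_entropy or frame.case_id or "ovarisk-frame"]
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=entropy + ["sop"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid(entropy_srcs=entropy + ["study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=entropy + ["series"])
    ds.Modality = "OT"
    ds.PatientID = frame.case_id
    ds.PatientName = frame.case_id
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{frame.pixel_spacing[0]:g}", f"{frame.pixel_spacing[1]:g}"]
    ds.PixelData = arr.tobytes()
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(path, enforce_file_format=True)
    return path


def write_frame_png(frame: Frame, path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG (physical spacing is not preserved)."""
    path = Path(path)
    arr = np.clip(np.rint(frame.pixels), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(path)
    return path


# ---------------------------------------------------------------------------
# contours


def write_contour_csv(contour: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.asarray(contour, dtype=float), columns=["x", "y"])
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_contour_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"{path}: contour CSV needs 'x' and 'y' columns")
    return df[["x", "y"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(records: list[CaseRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "case_id": r.case_id,
                "image_path": r.image_path,
                "contour_path": r.contour_path,
                "mass_type": r.annotation.mass_type,
                "shadow": int(r.annotation.shadow_present),
                "ca125": f"{r.clinical.ca125:.2f}",
                "menopausal": r.clinical.menopausal,
                "label": r.label if r.label is not None else "",
            }
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[CaseRecord]:
    """Read and validate a cohort manifest CSV.

    The ``label`` column is optional (absent at inference time); every other
    column is mandatory. Validation errors name the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in MANIFEST_COLUMNS if c != "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    has_label = "label" in df.columns
    records: list[CaseRecord] = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # 1-based line numbers incl. header
        mass_type = row["mass_type"].strip()
        if mass_type not in MASS_TYPES:
            raise ValueError(f"{where}: unknown mass_type {mass_type!r}")
        try:
            clinical = ClinicalRecord(ca125=float(row["ca125"]), menopausal=row["menopausal"].strip())
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        shadow = row["shadow"].strip().lower()
        if shadow not in {"0", "1", "true", "false"}:
            raise ValueError(f"{where}: shadow must be boolean-like, got {shadow!r}")
        label = row["label"].strip() if has_label else ""
        if label and label not in ("benign", "malignant"):
            raise ValueError(f"{where}: label must be benign/malignant, got {label!r}")
        contour_path = row["contour_path"].strip()
        contour = (
            read_contour_csv(path.parent / contour_path)
            if contour_path
            else np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        )
        annotation = MassAnnotation(
            mass_type=mass_type,
            contour=contour,
            shadow_present=shadow in {"1", "true"},
        )
        records.append(
            CaseRecord(
                case_id=row["case_id"],
                image_path=row["image_path"],
                contour_path=contour_path,
                annotation=annotation,
                clinical=clinical,
                label=label or None,
            )
        )
    return records
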