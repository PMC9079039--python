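"""Radiograph calibration and anatomical dimension records.

Clinical knee radiographs carry a metal calibration disc of known physical
diameter (30 mm in the imaging protocol emulated here) so that pixel
distances can be converted to millimetres despite projective magnification.
This module detects the disc on a grayscale raster, derives the pixel pitch,
and reads/validates the per-subject anatomical dimension records (the five
distances that drive atlas selection and morphing): maximum anterior-
posterior (AP) length of the medial and lateral femoral condyles, medial and
lateral tibiofemoral joint space width (JSW), and maximum medial-lateral
(ML) width of the distal femur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "CalibrationError",
    "ValidationError",
    "Modality",
    "CalibratedImage",
    "AnatomicalDimensions",
    "SubjectRecord",
    "detect_calibration_disc",
    "calibrate",
    "measure_distance",
    "load_subject_records",
    "write_subject_records",
    "mean_dimensions",
    "render_synthetic_radiograph",
    "SUBJECT_CSV_COLUMNS",
]

#: Physical diameter of the protocol calibration disc, mm.
PROTOCOL_DISC_DIAMETER_MM = 30.0

#: Minimum circularity 4*pi*A/P^2 for a connected component to count as the disc.
CIRCULARITY_MIN = 0.85

SUBJECT_CSV_COLUMNS = [
    "subject_id",
    "modality",
    "repeat",
    "ap_medial",
    "ap_lateral",
    "jsw_medial",
    "jsw_lateral",
    "ml_width",
    "body_weight",
]


class CalibrationError(ValueError):
    """Raised when disc detection or calibration fails."""


class ValidationError(ValueError):
    """Raised when a dimension record violates its invariants."""


class Modality(str, Enum):
    XRAY = "xray"
    MRI = "mri"


@dataclass(frozen=True)
class AnatomicalDimensions:
    """The five measured anatomical distances, in mm.

    Invariants: all positive; each JSW smaller than the AP length on its
    side; ML width larger than both JSWs.
    """

    ap_medial: float
    ap_lateral: float
    jsw_medial: float
    jsw_lateral: float
    ml_width: float

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValidationError("; ".join(errs))

    def validate(self) -> list[str]:
        errs = []
        for name in ("ap_medial", "ap_lateral", "jsw_medial", "jsw_lateral", "ml_width"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                errs.append(f"{name} must be finite and > 0, got {v!r}")
        if not errs:
            if self.jsw_medial >= self.ap_medial:
                errs.append("jsw_medial must be < ap_medial")
            if self.jsw_lateral >= self.ap_lateral:
                errs.append("jsw_lateral must be < ap_lateral")
            if self.ml_width <= max(self.jsw_medial, self.jsw_lateral):
                errs.append("ml_width must exceed both JSW values")
        return errs

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.ap_medial, self.ap_lateral, self.jsw_medial, self.jsw_lateral, self.ml_width]
        )

    def scaled(self, c: float) -> "AnatomicalDimensions":
        return AnatomicalDimensions(*(c * self.as_array()))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject x modality: body weight and >= 1 repeated measurements."""

    subject_id: str
    modality: Modality
    body_weight: float  # N
    repeats: tuple[AnatomicalDimensions, ...]

    def __post_init__(self) -> None:
        if not self.repeats:
            raise ValidationError(f"subject {self.subject_id}: repeats must be nonempty")
        if not (np.isfinite(self.body_weight) and self.body_weight > 0):
            raise ValidationError(f"subject {self.subject_id}: body_weight must be > 0")


@dataclass(frozen=True)
class CalibratedImage:
    """A grayscale raster with a known isotropic pixel pitch (mm/px)."""

    pixels: np.ndarray
    pixel_pitch: float
    scale_source: str = "disc"  # {"disc", "metadata"}

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError("pixels must be a 2-D raster with >= 2 rows and columns")
        if not (np.isfinite(self.pixel_pitch) and self.pixel_pitch > 0):
            raise ValidationError("pixel_pitch must be > 0")
        if self.scale_source not in ("disc", "metadata"):
            raise ValidationError("scale_source must be 'disc' or 'metadata'")


def detect_calibration_disc(image: np.ndarray) -> tuple[tuple[float, float], float]:
    """Locate the calibration disc on a grayscale raster.

    Pipeline: Otsu threshold -> connected components -> circularity filter
    (4*pi*A/P^2 >= 0.85) -> equivalent-circle diameter of the winning
    component.

    Parameters
    ----------
    image:
        2-D grayscale array containing exactly one high-contrast filled
        circle fully inside the frame.

    Returns
    -------
    (center_row, center_col), diameter_px

    Raises
    ------
    CalibrationError
        ``"no disc"`` when no sufficiently circular component exists;
        ``"ambiguous disc"`` when several components score similarly.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise CalibrationError("no disc: input is not a 2-D raster")
    if img.max() == img.min():
        raise CalibrationError("no disc: blank raster")
    thr = threshold_otsu(img)
    mask = img > thr
    # The disc is assumed brighter than background; if the bright phase covers
    # most of the frame the polarity is inverted.
    if mask.mean() > 0.5:
        mask = ~mask
    labels = measure.label(mask)
    candidates = []
    for region in measure.regionprops(labels):
        if region.area < 16:
            continue
        if region.perimeter == 0:
            continue
        circularity = 4.0 * math.pi * region.area / region.perimeter**2
        if circularity >= CIRCULARITY_MIN:
            candidates.append(region)
    if not candidates:
        raise CalibrationError("no disc: no circular component found")
    candidates.sort(key=lambda r: r.area, reverse=True)
    if len(candidates) > 1 and candidates[1].area > 0.5 * candidates[0].area:
        raise CalibrationError("ambiguous disc: multiple circular candidates of similar size")
    best = candidates[0]
    diameter = float(best.equivalent_diameter_area)
    center = (float(best.centroid[0]), float(best.centroid[1]))
    return center, diameter


def calibrate(disc_diameter_px: float, known_diameter_mm: float = PROTOCOL_DISC_DIAMETER_MM) -> float:
    """Pixel pitch (mm/px) from the detected disc diameter and its physical size."""
    if not (disc_diameter_px > 0 and known_diameter_mm > 0):
        raise CalibrationError("invalid calibration: both diameters must be > 0")
    return known_diameter_mm / disc_diameter_px


def measure_distance(
    image: CalibratedImage, p1: Sequence[float], p2: Sequence[float]
) -> float:
    """Physical distance (mm) between two pixel coordinates on a calibrated image."""
    nrow, ncol = image.pixels.shape
    for p in (p1, p2):
        if not (0 <= p[0] <= nrow - 1 and 0 <= p[1] <= ncol - 1):
            raise ValueError(f"point {tuple(p)} outside raster {image.pixels.shape}")
    d_px = math.hypot(p1[0] - p2[0], p1[1] - p2[1])
    return d_px * image.pixel_pitch


def render_synthetic_radiograph(
    disc_diameter_mm: float = PROTOCOL_DISC_DIAMETER_MM,
    pixel_pitch: float = 0.148,
    shape: tuple[int, int] | None = None,
    center: tuple[float, float] | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a synthetic posterior-anterior radiograph with a calibration disc.

    The disc is an antialiased filled circle (analytic coverage at the rim)
    on a dark background, optionally with additive Gaussian noise expressed
    as a fraction of the dynamic range. The frame defaults to 512 px square
    or 1.5x the disc diameter, whichever is larger.
    """
    if shape is None:
        side = max(512, int(np.ceil(1.5 * disc_diameter_mm / pixel_pitch)))
        shape = (side, side)
    nrow, ncol = shape
    if center is None:
        center = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    radius_px = 0.5 * disc_diameter_mm / pixel_pitch
    if radius_px * 2 + 4 > min(shape):
        raise ValueError("disc does not fit inside the frame")
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    dist = np.hypot(rr - center[0], cc - center[1])
    # soft 1-px rim so the equivalent-area diameter is unbiased
    img = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng() if rng is None else rng
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img


def mean_dimensions(record: SubjectRecord) -> AnatomicalDimensions:
    """Arithmetic mean of the repeated measurements, field by field."""
    arr = np.mean([r.as_array() for r in record.repeats], axis=0)
    return AnatomicalDimensions(*arr)


def load_subject_records(path: str | Path) -> list[SubjectRecord]:
    """Read per-subject dimension records from CSV.

    Expected header: subject_id, modality, repeat, ap_medial, ap_lateral,
    jsw_medial, jsw_lateral, ml_width, body_weight. Rows are grouped by
    subject x modality (sorted by the repeat column); every row is validated
    and all violations are accumulated into a single report.
    """
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"format error: missing columns {missing}")
    errors: list[str] = []
    records: list[SubjectRecord] = []
    for (sid, modality), group in df.groupby(["subject_id", "modality"], sort=True):
        group = group.sort_values("repeat")
        repeats = []
        for _, row in group.iterrows():
            try:
                repeats.append(
                    AnatomicalDimensions(
                        ap_medial=float(row["ap_medial"]),
                        ap_lateral=float(row["ap_lateral"]),
                        jsw_medial=float(row["jsw_medial"]),
                        jsw_lateral=float(row["jsw_lateral"]),
                        ml_width=float(row["ml_width"]),
                    )
                )
            except ValidationError as e:
                errors.append(f"subject {sid} ({modality}) repeat {row['repeat']}: {e}")
        bw = float(group["body_weight"].iloc[0])
        if repeats and not errors:
            try:
                records.append(
                    SubjectRecord(
                        subject_id=str(sid),
                        modality=Modality(str(modality)),
                        body_weight=bw,
                        repeats=tuple(repeats),
                    )
                )
            except (ValidationError, ValueError) as e:
                errors.append(f"subject {sid} ({modality}): {e}")
    if errors:
        raise ValidationError("invalid records:\n" + "\n".join(errors))
    return records


def write_subject_records(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Inverse of :func:`load_subject_records` on valid record lists."""
    rows = []
    for rec in records:
        for i, d in enumerate(rec.repeats, start=1):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "modality": rec.modality.value,
                    "repeat": i,
                    "ap_medial": d.ap_medial,
                    "ap_lateral": d.ap_lateral,
                    "jsw_medial": d.jsw_medial,
                    "jsw_lateral": d.jsw_lateral,
                    "ml_width": d.ml_width,
                    "body_weight": rec.body_weight,
                }
            )
    pd.DataFrame(rows, columns=SUBJECT_CSV_COLUMNS).to_csv(path, index=False)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF grayscale image as a float array."""
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=float)
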