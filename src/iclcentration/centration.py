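"""Calibrated centration metrics in the anatomic coordinate frame.

The corneal center (intersection of the limbus ellipse's longest horizontal
and vertical chords, i.e. its center) is the origin.  After mirroring left
eyes, +x points nasally and +y superiorly, so offsets pool across right and
left eyes.  Pixel offsets are converted to mm with the white-to-white (WTW)
magnification: mm/px = WTW / (horizontal limbus diameter in px).  Distances
use D = sqrt(x^2 + y^2).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale

from .errors import InputError
from .segmentation import EllipseParams, SegmentationResult

__all__ = [
    "Calibration",
    "CentrationRecord",
    "calibrate",
    "to_anatomic_frame",
    "compute_distances",
    "classify_quadrant",
    "normalize_to_hole",
    "RECORD_COLUMNS",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-mm scale factors for one image.

    ``magnification_mm_per_px`` carries the WTW magnification used for every
    reported distance; ``hole_norm_px`` records the measured pixel diameter
    of the 360-um hole for parity with hole-fixed image normalization.
    """

    wtw_mm: float
    corneal_horizontal_px: float
    magnification_mm_per_px: float
    hole_norm_px: float = 7.5

    def px_to_mm(self, d_px: float) -> float:
        return d_px * self.magnification_mm_per_px


def calibrate(limbus: EllipseParams, hole: EllipseParams | None, wtw_mm: float) -> Calibration:
    """Derive the mm-per-px magnification from the limbus and biometer WTW."""
    if not 9.0 <= wtw_mm <= 14.0:
        raise InputError(f"wtw_mm = {wtw_mm} outside the plausible range [9, 14] mm")
    d_px = limbus.horizontal_diameter_px
    if d_px <= 0:
        raise InputError("limbus horizontal diameter must be positive")
    return Calibration(
        wtw_mm=float(wtw_mm),
        corneal_horizontal_px=float(d_px),
        magnification_mm_per_px=float(wtw_mm) / float(d_px),
        hole_norm_px=float(hole.mean_diameter_px) if hole is not None else 7.5,
    )


def normalize_to_hole(image: np.ndarray, hole_diameter_px: float, target_px: float = 7.5) -> np.ndarray:
    """Resize an image so the central hole spans ``target_px`` pixels.

    Optional preprocessing for parity with hole-fixed normalization
    workflows; the WTW magnification makes it mathematically redundant for
    mm-valued outputs.
    """
    if hole_diameter_px <= 0:
        raise InputError("hole_diameter_px must be positive")
    return rescale(image, target_px / hole_diameter_px, preserve_range=True, anti_aliasing=True)


@dataclass
class CentrationRecord:
    """Per-eye signed coordinates and derived centration metrics (mm).

    Coordinates are in the anatomic frame (origin = corneal center, +x nasal,
    +y superior).  ``d_*`` are Euclidean distances, ``dhx/dhy/dpx/dpy``
    unsigned component magnitudes, ``dhpx/dhpy`` the signed components of the
    hole-minus-pupil vector.
    """

    eye_id: str
    laterality: str
    x_hole_mm: float
    y_hole_mm: float
    x_pupil_mm: float
    y_pupil_mm: float
    d_hc_mm: float = math.nan
    d_pc_mm: float = math.nan
    d_hp_mm: float = math.nan
    dhx_mm: float = math.nan
    dhy_mm: float = math.nan
    dpx_mm: float = math.nan
    dpy_mm: float = math.nan
    dhpx_mm: float = math.nan
    dhpy_mm: float = math.nan
    quadrant_hc: str = ""
    quadrant_hp: str = ""
    quadrant_pc: str = ""
    boundary_hc: bool = False
    boundary_hp: bool = False
    boundary_pc: bool = False
    kappa_x_mm: float = math.nan
    kappa_y_mm: float = math.nan

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


RECORD_COLUMNS = [f.name for f in dataclasses.fields(CentrationRecord)]


def classify_quadrant(vector_mm: tuple[float, float]) -> tuple[str, bool]:
    """Quadrant label of a signed offset vector, plus a boundary flag.

    ``y >= 0`` reads superior (else inferior); ``x >= 0`` reads nasal (else
    temporal).  A component exactly at zero is a boundary case: the label is
    assigned deterministically (superior/nasal) and flagged.
    """
    x, y = vector_mm
    vert = "superior" if y >= 0 else "inferior"
    horiz = "nasal" if x >= 0 else "temporal"
    return f"{vert}-{horiz}", bool(x == 0 or y == 0)


def to_anatomic_frame(
    seg: SegmentationResult,
    cal: Calibration,
    laterality: str,
    eye_id: str = "",
    kappa_offset_mm: tuple[float, float] | None = None,
) -> CentrationRecord:
    """Express the hole and pupil centers in mm relative to the corneal center.

    Raster y is negated so +y is superior.  For right eyes raster +x already
    points nasally in our convention; left-eye images are expected in their
    native (mirrored) orientation, so their x-offsets are negated, mapping
    both eyes onto the common nasal/temporal axis.
    """
    if laterality not in ("OD", "OS"):
        raise InputError(f"laterality must be OD or OS, got {laterality!r}")
    if seg.flags and not seg.flags.get("pupil_inside_limbus", True):
        raise InputError("segmentation failed quality check: pupil outside limbus")
    sx = 1.0 if laterality == "OD" else -1.0
    m = cal.magnification_mm_per_px
    lx, ly = seg.limbus.center_px

    def convert(center_px: tuple[float, float]) -> tuple[float, float]:
        return (sx * (center_px[0] - lx) * m, -(center_px[1] - ly) * m)

    xh, yh = convert(seg.hole.center_px)
    xp, yp = convert(seg.pupil.center_px)
    rec = CentrationRecord(
        eye_id=eye_id, laterality=laterality,
        x_hole_mm=xh, y_hole_mm=yh, x_pupil_mm=xp, y_pupil_mm=yp,
    )
    if kappa_offset_mm is not None:
        rec.kappa_x_mm, rec.kappa_y_mm = kappa_offset_mm
    return rec


def compute_distances(record: CentrationRecord) -> CentrationRecord:
    """Fill every derived distance, component, and quadrant label in place."""
    xh, yh = record.x_hole_mm, record.y_hole_mm
    xp, yp = record.x_pupil_mm, record.y_pupil_mm
    for v in (xh, yh, xp, yp):
        if math.isnan(v):
            raise InputError("record coordinates must be set before computing distances")
    record.d_hc_mm = math.hypot(xh, yh)
    record.d_pc_mm = math.hypot(xp, yp)
    record.dhpx_mm = xh - xp
    record.dhpy_mm = yh - yp
    record.d_hp_mm = math.hypot(record.dhpx_mm, record.dhpy_mm)
    record.dhx_mm, record.dhy_mm = abs(xh), abs(yh)
    record.dpx_mm, record.dpy_mm = abs(xp), abs(yp)
    record.quadrant_hc, record.boundary_hc = classify_quadrant((xh, yh))
    record.quadrant_pc, record.boundary_pc = classify_quadrant((xp, yp))
    record.quadrant_hp, record.boundary_hp = classify_quadrant((record.dhpx_mm, record.dhpy_mm))
    return record
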