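"""End-to-end per-eye processing: image -> calibrated centration record."""

from __future__ import annotations

import math

from .centration import (
    CentrationRecord,
    calibrate,
    compute_distances,
    to_anatomic_frame,
)
from .segmentation import SegmentationConfig, segment_eye
from .simulate import EyeGeometry

__all__ = ["process_eye", "record_from_geometry"]


def process_eye(
    image,
    *,
    wtw_mm: float,
    laterality: str,
    eye_id: str = "",
    kappa_offset_mm: tuple[float, float] | None = None,
    cfg: SegmentationConfig | None = None,
) -> CentrationRecord:
    """Segment one image, calibrate with the biometer WTW, and derive all metrics."""
    seg = segment_eye(image, cfg, wtw_mm=wtw_mm)
    cal = calibrate(seg.limbus, seg.hole, wtw_mm)
    rec = to_anatomic_frame(seg, cal, laterality, eye_id=eye_id, kappa_offset_mm=kappa_offset_mm)
    return compute_distances(rec)


def record_from_geometry(geom: EyeGeometry) -> CentrationRecord:
    """Centration record straight from ground-truth geometry (no imaging).

    Used to study the distance statistics of a sampled cohort in isolation
    from segmentation error.
    """
    rec = CentrationRecord(
        eye_id=geom.eye_id,
        laterality=geom.laterality,
        x_hole_mm=geom.hole_center_mm[0],
        y_hole_mm=geom.hole_center_mm[1],
        x_pupil_mm=geom.pupil_center_mm[0],
        y_pupil_mm=geom.pupil_center_mm[1],
    )
    kx, ky = geom.kappa_offset_mm
    if not (math.isnan(kx) or math.isnan(ky)):
        rec.kappa_x_mm, rec.kappa_y_mm = kx, ky
    return compute_distances(rec)
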