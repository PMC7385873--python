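"""Locating the limbus, pupil, and ICL central-hole ellipses in en-face eye images.

Pixel coordinates follow the raster convention throughout: origin at the
top-left pixel center, ``x`` increasing rightward (columns), ``y`` increasing
downward (rows).  Conversion to the anatomic (nasal/superior) frame happens
only in :mod:`iclcentration.centration`.

The ellipse fit is the direct least-squares conic fit with the ellipse
constraint ``4AC - B^2 = 1`` (Fitzgibbon et al.), in the numerically stable
block decomposition of Halir & Flusser.  Its algebraic center coincides with
the intersection of the ellipse's longest horizontal and vertical chords,
which is how the corneal and pupil centers are defined clinically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import gaussian, threshold_multiotsu
from skimage.measure import find_contours, label, points_in_poly, regionprops
from skimage.morphology import disk

from .errors import DetectionError, FitError

__all__ = [
    "EllipseParams",
    "SegmentationConfig",
    "SegmentationResult",
    "fit_ellipse",
    "fit_ellipse_ransac",
    "detect_pupil",
    "detect_limbus",
    "detect_hole",
    "segment_eye",
]


# ---------------------------------------------------------------------------
# Ellipse parameters and conic algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseParams:
    """Geometric parameters of a fitted ellipse in pixel coordinates.

    ``semi_axes_px`` is ordered ``(a, b)`` with ``a >= b``; ``rotation_rad``
    is the angle of the major axis measured from the raster +x axis,
    normalized to ``[0, pi)``.
    """

    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]
    rotation_rad: float
    rms_residual_px: float = 0.0
    n_support_points: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if not (a >= b > 0):
            raise FitError(f"invalid semi-axes (a, b) = ({a}, {b}); need a >= b > 0")
        if self.rms_residual_px < 0:
            raise FitError("rms residual must be non-negative")

    # -- conic form -------------------------------------------------------
    def conic(self) -> np.ndarray:
        """Coefficients (A, B, C, D, E, F) of A x^2 + B xy + C y^2 + D x + E y + F = 0."""
        x0, y0 = self.center_px
        a, b = self.semi_axes_px
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        A = ct**2 / a**2 + st**2 / b**2
        C = st**2 / a**2 + ct**2 / b**2
        B = 2 * ct * st * (1 / a**2 - 1 / b**2)
        D = -(2 * A * x0 + B * y0)
        E = -(B * x0 + 2 * C * y0)
        F = A * x0**2 + B * x0 * y0 + C * y0**2 - 1.0
        return np.array([A, B, C, D, E, F])

    def point(self, t: np.ndarray) -> np.ndarray:
        """Boundary points at parameter angles ``t`` (shape (n, 2), x-y order)."""
        a, b = self.semi_axes_px
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        u, v = a * np.cos(t), b * np.sin(t)
        return np.column_stack(
            [self.center_px[0] + u * ct - v * st, self.center_px[1] + u * st + v * ct]
        )

    def normalized_radius(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Elliptical radius: 1 on the boundary, < 1 inside."""
        dx, dy = np.asarray(x) - self.center_px[0], np.asarray(y) - self.center_px[1]
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        a, b = self.semi_axes_px
        return np.sqrt((u / a) ** 2 + (v / b) ** 2)

    def contains(self, x: float, y: float, scale: float = 1.0) -> bool:
        return bool(self.normalized_radius(x, y) <= scale)

    @property
    def horizontal_diameter_px(self) -> float:
        """Length of the longest horizontal chord (the ellipse's x-extent)."""
        a, b = self.semi_axes_px
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return 2.0 * float(np.sqrt((a * ct) ** 2 + (b * st) ** 2))

    @property
    def vertical_diameter_px(self) -> float:
        a, b = self.semi_axes_px
        ct, st = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return 2.0 * float(np.sqrt((a * st) ** 2 + (b * ct) ** 2))

    @property
    def mean_diameter_px(self) -> float:
        return float(sum(self.semi_axes_px))

    def interior_mask(self, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.normalized_radius(xx, yy) <= scale

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_px"] = list(d["center_px"])
        d["semi_axes_px"] = list(d["semi_axes_px"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseParams":
        return cls(
            center_px=tuple(d["center_px"]),
            semi_axes_px=tuple(d["semi_axes_px"]),
            rotation_rad=float(d["rotation_rad"]),
            rms_residual_px=float(d.get("rms_residual_px", 0.0)),
            n_support_points=int(d.get("n_support_points", 0)),
        )


def sampson_distance(conic: np.ndarray, points: np.ndarray) -> np.ndarray:
    """First-order geometric distance of points to a conic (px)."""
    A, B, C, D, E, F = conic
    x, y = points[:, 0], points[:, 1]
    f = A * x**2 + B * x * y + C * y**2 + D * x + E * y + F
    gx = 2 * A * x + B * y + D
    gy = B * x + 2 * C * y + E
    g = np.hypot(gx, gy)
    return np.abs(f) / np.maximum(g, 1e-300)


def _conic_to_params(c: np.ndarray, points: np.ndarray) -> EllipseParams:
    A, B, C, D, E, F = c
    if B * B - 4 * A * C >= 0:
        raise FitError("fitted conic is not an ellipse")
    if A + C < 0:  # normalize sign so the quadratic form is positive definite
        c = -c
        A, B, C, D, E, F = c
    M = np.array([[A, B / 2], [B / 2, C]])
    center = np.linalg.solve(2 * M, [-D, -E])
    x0, y0 = center
    qc = A * x0**2 + B * x0 * y0 + C * y0**2 + D * x0 + E * y0 + F
    k = -qc
    if k <= 0:
        raise FitError("degenerate (point or imaginary) ellipse")
    evals, evecs = np.linalg.eigh(M)
    semi = np.sqrt(k / evals)  # ascending evals -> descending axes
    a, b = semi[0], semi[1]
    vec = evecs[:, 0]  # eigenvector of the smaller eigenvalue = major axis
    rot = float(np.arctan2(vec[1], vec[0])) % np.pi
    resid = sampson_distance(c, points)
    return EllipseParams(
        center_px=(float(x0), float(y0)),
        semi_axes_px=(float(a), float(b)),
        rotation_rad=rot,
        rms_residual_px=float(np.sqrt(np.mean(resid**2))),
        n_support_points=len(points),
    )


def _fit_conic(points: np.ndarray) -> np.ndarray:
    """Halir-Flusser stable direct least-squares conic fit; points pre-conditioned."""
    x, y = points[:, 0], points[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    evecs = np.real_if_close(evecs, tol=1e6)
    if np.iscomplexobj(evecs):
        evecs = evecs.real
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    valid = np.where(cond > 0)[0]
    if len(valid) == 0:
        raise FitError("no ellipse satisfies the conic constraint for these points")
    a1 = evecs[:, valid[0]]
    a2 = T @ a1
    return np.concatenate([a1, a2])


def fit_ellipse(points: Sequence[Sequence[float]] | np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to 2-D points (x, y order).

    On exact ellipse samples the construction parameters are recovered to
    numerical precision.  Raises :class:`FitError` for fewer than 5 distinct
    points or degenerate (e.g. collinear) configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be an (n, 2) array")
    if len(np.unique(pts, axis=0)) < 5:
        raise FitError("at least 5 distinct points are required")
    # Condition: shift to centroid, scale to unit RMS radius.
    mu = pts.mean(axis=0)
    scale = np.sqrt(np.mean(np.sum((pts - mu) ** 2, axis=1)))
    if scale <= 0:
        raise FitError("all points coincide")
    norm = (pts - mu) / scale
    conic_n = _fit_conic(norm)
    p = _conic_to_params(conic_n, norm)
    out = EllipseParams(
        center_px=(p.center_px[0] * scale + mu[0], p.center_px[1] * scale + mu[1]),
        semi_axes_px=(p.semi_axes_px[0] * scale, p.semi_axes_px[1] * scale),
        rotation_rad=p.rotation_rad,
        rms_residual_px=0.0,
        n_support_points=len(pts),
    )
    resid = sampson_distance(out.conic(), pts)
    return dataclasses.replace(out, rms_residual_px=float(np.sqrt(np.mean(resid**2))))


def fit_ellipse_ransac(
    points: np.ndarray,
    *,
    n_iter: int = 100,
    inlier_tol_px: float = 1.0,
    min_samples: int = 8,
    seed: int = 0,
) -> EllipseParams:
    """Random-sample-consensus ellipse fit, robust to outlying edge points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < min_samples:
        return fit_ellipse(pts)
    rng = np.random.default_rng(seed)
    best_mask = None
    best_score = -1.0
    for _ in range(n_iter):
        idx = rng.choice(len(pts), size=min_samples, replace=False)
        try:
            cand = fit_ellipse(pts[idx])
        except FitError:
            continue
        resid = sampson_distance(cand.conic(), pts)
        mask = resid < inlier_tol_px
        score = mask.sum() - resid[mask].mean() / inlier_tol_px if mask.any() else 0.0
        if score > best_score:
            best_score, best_mask = score, mask
    if best_mask is None or best_mask.sum() < 5:
        return fit_ellipse(pts)
    return fit_ellipse(pts[best_mask])


# ---------------------------------------------------------------------------
# Structure detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable detection bounds (all lengths in pixels)."""

    min_pupil_px: float = 15.0       # min plausible pupil diameter
    max_pupil_px: float = 160.0
    min_limbus_px: float = 80.0
    hole_diameter_px_prior: float = 7.5   # 360 um at 48 um/px
    hole_tol: float = 0.2                 # relative tolerance on ring diameter
    ring_width_px: float = 1.5
    ransac_iters: int = 100
    ransac_tol_px: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class SegmentationResult:
    limbus: EllipseParams
    pupil: EllipseParams
    hole: EllipseParams
    flags: dict

    def to_dict(self) -> dict:
        return {
            "limbus": self.limbus.to_dict(),
            "pupil": self.pupil.to_dict(),
            "hole": self.hole.to_dict(),
            "flags": dict(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationResult":
        return cls(
            limbus=EllipseParams.from_dict(d["limbus"]),
            pupil=EllipseParams.from_dict(d["pupil"]),
            hole=EllipseParams.from_dict(d["hole"]),
            flags=dict(d.get("flags", {})),
        )


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(lab, keep)


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DetectionError("expected a 2-D grayscale image")
    return img


def flatten_illumination(image: np.ndarray) -> np.ndarray:
    """Divide out a least-squares plane fit to the intensity field.

    The slit-lamp's oblique diffuse illumination appears as a roughly linear
    multiplicative gradient; removing it stabilizes global thresholds.
    """
    img = _as_float(image)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    A = np.column_stack([np.ones(img.size), xx.ravel() / w, yy.ravel() / h])
    coef, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
    bg = (A @ coef).reshape(img.shape)
    mean = bg.mean()
    if mean <= 0:
        return img
    bg = np.maximum(bg / mean, 1e-3)
    return img / bg


def _multiotsu(img: np.ndarray) -> np.ndarray:
    try:
        return threshold_multiotsu(img, classes=3)
    except ValueError as exc:
        raise DetectionError("image has too little intensity structure to threshold") from exc


def _closed_contours_around(
    img: np.ndarray, iso: float, point_xy: tuple[float, float], min_len: int = 12
) -> list[np.ndarray]:
    """Closed iso-contours (row, col arrays) that enclose ``point_xy``."""
    out = []
    for c in find_contours(img, iso):
        if len(c) < min_len or not np.allclose(c[0], c[-1]):
            continue
        if points_in_poly(np.array([[point_xy[1], point_xy[0]]]), c)[0]:
            out.append(c)
    return out


def _contour_points_xy(contour_rc: np.ndarray) -> np.ndarray:
    return contour_rc[:, ::-1]


def detect_pupil(image: np.ndarray, cfg: SegmentationConfig | None = None) -> EllipseParams:
    """Locate the pupil as the dominant dark elliptical region.

    Thresholding uses 3-class Otsu on the illumination-flattened image; the
    boundary is localized at sub-pixel precision by tracing the iso-contour
    midway between the pupil and iris intensity levels.
    """
    cfg = cfg or SegmentationConfig()
    img = _as_float(image)
    sm = gaussian(img, sigma=1.0, preserve_range=True)
    fl = flatten_illumination(sm)
    t_low, _ = _multiotsu(fl)
    mask = fl < t_low
    mask = ndi.binary_closing(mask, structure=disk(3))
    mask = ndi.binary_fill_holes(mask)
    min_area = int(np.pi * (cfg.min_pupil_px / 2) ** 2 * 0.5)
    mask = _remove_small(mask, max(min_area, 8))
    regions = [
        r
        for r in regionprops(label(mask))
        if cfg.min_pupil_px <= r.equivalent_diameter_area <= cfg.max_pupil_px
    ]
    if not regions:
        raise DetectionError(
            f"no pupil candidate with diameter in [{cfg.min_pupil_px}, {cfg.max_pupil_px}] px"
        )
    region = max(regions, key=lambda r: r.area)
    rmask = label(mask) == region.label
    core = ndi.binary_erosion(rmask, structure=disk(2))
    if not core.any():
        core = rmask
    m_in = float(np.median(fl[core]))
    ring_zone = ndi.binary_dilation(rmask, structure=disk(6)) & ~ndi.binary_dilation(rmask, structure=disk(2))
    m_out = float(np.median(fl[ring_zone])) if ring_zone.any() else float(np.median(fl[~rmask]))
    iso = 0.5 * (m_in + m_out)
    cy, cx = region.centroid
    contours = _closed_contours_around(fl, iso, (cx, cy))
    if not contours:
        raise DetectionError("pupil boundary contour not found at the expected iso-level")
    expected = np.pi * region.equivalent_diameter_area
    contour = min(contours, key=lambda c: abs(len(c) - expected))
    ellipse = fit_ellipse(_contour_points_xy(contour))
    if not cfg.min_pupil_px / 2 <= ellipse.semi_axes_px[0] <= cfg.max_pupil_px:
        raise DetectionError("fitted pupil ellipse outside plausible size bounds")
    return ellipse


def detect_limbus(image: np.ndarray, cfg: SegmentationConfig | None = None) -> EllipseParams:
    """Locate the corneal limbus (iris/sclera boundary) ellipse.

    The boundary iso-contour is fitted by random-sample consensus so that the
    oblique illumination gradient, which biases a fraction of edge points,
    does not drag the fit.
    """
    cfg = cfg or SegmentationConfig()
    img = _as_float(image)
    sm = gaussian(img, sigma=2.0, preserve_range=True)
    fl = flatten_illumination(sm)
    t_low, t_high = _multiotsu(fl)
    mask = fl < t_high
    mask = ndi.binary_closing(mask, structure=disk(5))
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, int(np.pi * (cfg.min_limbus_px / 2) ** 2 * 0.25))
    lab = label(mask)
    regions = [r for r in regionprops(lab) if r.equivalent_diameter_area >= cfg.min_limbus_px]
    if not regions:
        raise DetectionError("no limbus-scale dark region found")
    region = max(regions, key=lambda r: r.area)
    h, w = img.shape
    minr, minc, maxr, maxc = region.bbox
    if minr == 0 or minc == 0 or maxr == h or maxc == w:
        raise DetectionError("limbus region touches the frame border (cornea not fully imaged)")
    rmask = lab == region.label
    iris = rmask & (fl >= t_low)
    m_iris = float(np.median(fl[iris])) if iris.any() else float(np.median(fl[rmask]))
    outside = ~ndi.binary_dilation(rmask, structure=disk(4))
    m_sclera = float(np.median(fl[outside]))
    if m_sclera <= m_iris:
        raise DetectionError("no iris/sclera contrast found")
    iso = 0.5 * (m_iris + m_sclera)
    cy, cx = region.centroid
    contours = _closed_contours_around(fl, iso, (cx, cy))
    if not contours:
        raise DetectionError("limbus boundary contour not found")
    expected = np.pi * region.equivalent_diameter_area
    contour = min(contours, key=lambda c: abs(len(c) - expected))
    return fit_ellipse_ransac(
        _contour_points_xy(contour),
        n_iter=cfg.ransac_iters,
        inlier_tol_px=cfg.ransac_tol_px,
        seed=cfg.seed,
    )


def detect_hole(
    image: np.ndarray,
    pupil: EllipseParams,
    cfg: SegmentationConfig | None = None,
    diameter_px_prior: float | None = None,
) -> EllipseParams:
    """Locate the 360-um central-hole ring of the implanted lens inside the pupil.

    The ring appears as a bright annulus against the dark pupil.  Both ring
    edges are traced as sub-pixel iso-contours and fitted; the reported
    ellipse is their average, i.e. the ring centerline, whose diameter must
    lie within ``hole_tol`` of the calibrated 360-um prior.
    """
    cfg = cfg or SegmentationConfig()
    prior = diameter_px_prior if diameter_px_prior is not None else cfg.hole_diameter_px_prior
    img = _as_float(image)
    fl = flatten_illumination(gaussian(img, sigma=0.8, preserve_range=True))
    inside = pupil.interior_mask(img.shape, scale=0.98)
    if inside.sum() < 16:
        raise DetectionError("pupil interior too small to search for the central hole")
    vals = fl[inside]
    m_p = float(np.median(vals))
    p99 = float(np.percentile(vals, 99))
    span = float(np.percentile(fl, 95)) - m_p
    if span <= 0 or (p99 - m_p) < 0.25 * span:
        raise DetectionError("no bright ring structure inside the pupil")
    bright = inside & (fl > 0.5 * (m_p + p99))
    lab = label(bright)
    candidates: list[EllipseParams] = []
    for region in regionprops(lab):
        if region.area < 4:
            continue
        minr, minc, maxr, maxc = region.bbox
        d_est = max(maxr - minr, maxc - minc)
        if not 0.4 * prior <= d_est <= 2.5 * prior:
            continue
        cy, cx = region.centroid
        pad = int(np.ceil(prior + 4))
        r0, r1 = max(0, int(cy) - pad), min(img.shape[0], int(cy) + pad + 1)
        c0, c1 = max(0, int(cx) - pad), min(img.shape[1], int(cx) + pad + 1)
        window = fl[r0:r1, c0:c1]
        comp_med = float(np.median(fl[lab == region.label]))
        iso = 0.5 * (m_p + comp_med)
        local = _closed_contours_around(window, iso, (cx - c0, cy - r0), min_len=8)
        fits = []
        for c in local:
            pts = _contour_points_xy(c) + [c0, r0]
            try:
                fits.append(fit_ellipse(pts))
            except FitError:
                continue
        if not fits:
            continue
        fits.sort(key=lambda e: e.mean_diameter_px, reverse=True)
        outer = fits[0]
        if len(fits) >= 2:
            inner = fits[-1]
            center = (
                0.5 * (outer.center_px[0] + inner.center_px[0]),
                0.5 * (outer.center_px[1] + inner.center_px[1]),
            )
            axes = (
                0.5 * (outer.semi_axes_px[0] + inner.semi_axes_px[0]),
                0.5 * (outer.semi_axes_px[1] + inner.semi_axes_px[1]),
            )
        else:
            # Only one ring edge resolved (the other can merge into the iris
            # when the hole sits at the pupil margin).  The contour still
            # centers the ring accurately; take the diameter from the
            # intensity-weighted mean radius of the bright crest instead.
            center = outer.center_px
            rows, cols = np.nonzero(lab == region.label)
            weights = np.maximum(fl[rows, cols] - m_p, 0.0)
            radii = np.hypot(cols - center[0], rows - center[1])
            if weights.sum() <= 0:
                continue
            r_mean = float(np.average(radii, weights=weights))
            axes = (r_mean, r_mean)
        if axes[1] <= 0:
            continue
        n_pts = outer.n_support_points + (fits[-1].n_support_points if len(fits) >= 2 else 0)
        cand = EllipseParams(
            center_px=center,
            semi_axes_px=(max(axes), min(axes)),
            rotation_rad=outer.rotation_rad,
            rms_residual_px=outer.rms_residual_px,
            n_support_points=n_pts,
        )
        if abs(cand.mean_diameter_px - prior) <= cfg.hole_tol * prior and pupil.contains(
            *cand.center_px
        ):
            candidates.append(cand)
    if not candidates:
        raise DetectionError(
            f"no central-hole ring with diameter within {cfg.hole_tol:.0%} of {prior:.2f} px"
        )
    return min(candidates, key=lambda e: abs(e.mean_diameter_px - prior))


def segment_eye(
    image: np.ndarray,
    cfg: SegmentationConfig | None = None,
    wtw_mm: float | None = None,
) -> SegmentationResult:
    """Run the full detection chain: limbus, pupil, then central hole.

    If ``wtw_mm`` (the biometer white-to-white distance) is given, the
    expected hole diameter in pixels is derived from the detected limbus
    instead of assuming the default 48 um/px acquisition scale.
    """
    cfg = cfg or SegmentationConfig()
    limbus = detect_limbus(image, cfg)
    pupil = detect_pupil(image, cfg)
    prior = cfg.hole_diameter_px_prior
    if wtw_mm is not None:
        prior = 0.360 * limbus.horizontal_diameter_px / wtw_mm
    hole = detect_hole(image, pupil, cfg, diameter_px_prior=prior)
    flags = {
        "pupil_inside_limbus": limbus.contains(*pupil.center_px),
        "hole_inside_pupil": pupil.contains(*hole.center_px),
        "hole_diameter_px": hole.mean_diameter_px,
    }
    return SegmentationResult(limbus=limbus, pupil=pupil, hole=hole, flags=flags)
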