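"""Synthetic anterior-segment cohorts and slit-lamp-like grayscale renders.

The generator samples per-eye ground-truth geometry — corneal (limbus)
ellipse, pupil ellipse, and the 360-um central hole of an implanted
posterior-chamber phakic lens — and can rasterize each eye as a grayscale
image resembling a diffusely illuminated slit-lamp photograph.  Every render
carries a sidecar record with all ground-truth centers in pixel coordinates,
so the segmentation and centration stages can be validated end-to-end
against known truth.

Offset model
------------
The hole-to-corneal-center and pupil-to-corneal-center vectors are sampled
componentwise: unsigned x/y magnitudes from normals truncated at zero
(defaults are the cohort means +/- SD of an 89-eye clinical series: hole
0.16 +/- 0.12 / 0.30 +/- 0.19 mm, pupil 0.28 +/- 0.19 / 0.27 +/- 0.14 mm),
and signs from Bernoulli draws (the hole sits superiorly in ~95.5% of eyes
with a near-even nasal/temporal split; the pupil sits superonasally in
~95.5%).  Hole and pupil magnitudes are coupled through a Gaussian copula
targeting the observed Spearman rank correlations (0.57 horizontally, 0.42
vertically).  Kappa offsets (pupil offset from the corneal vertex) are
normal and rank-coupled to the hole-minus-pupil vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, RenderError

__all__ = [
    "CohortParams",
    "EyeGeometry",
    "RenderConfig",
    "RenderRecord",
    "sample_cohort",
    "render_eye",
    "mirror_image",
    "spearman_to_pearson",
]

HOLE_DIAMETER_UM = 360.0


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman rho is ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Population parameters for sampling a cohort of implanted eyes.

    Magnitude means/SDs parameterize the *untruncated* normal; truncation at
    zero shifts the realized sample mean slightly upward (folded-normal
    effect).  All lengths in mm.
    """

    n_eyes: int = 89
    # hole-vs-corneal-center component magnitudes
    hole_x_mag_mean: float = 0.16
    hole_x_mag_sd: float = 0.12
    hole_y_mag_mean: float = 0.30
    hole_y_mag_sd: float = 0.19
    # pupil-vs-corneal-center component magnitudes
    pupil_x_mag_mean: float = 0.28
    pupil_x_mag_sd: float = 0.19
    pupil_y_mag_mean: float = 0.27
    pupil_y_mag_sd: float = 0.14
    # sign probabilities (+x nasal, +y superior)
    hole_p_superior: float = 0.955
    hole_p_nasal: float = 0.506
    pupil_p_superior: float = 0.955
    pupil_p_nasal: float = 0.955
    # Spearman rank-correlation targets between paired hole/pupil magnitudes
    rho_x: float = 0.57
    rho_y: float = 0.42
    # ocular dimensions
    wtw_mean: float = 10.28
    wtw_sd: float = 0.70
    corneal_vertical_mean: float = 9.69
    corneal_vertical_sd: float = 0.59
    pupil_diam_h_mean: float = 2.54
    pupil_diam_h_sd: float = 0.57
    pupil_diam_v_mean: float = 2.43
    pupil_diam_v_sd: float = 0.56
    # kappa (pupil-offset) marginals and rank coupling to the hole-pupil vector
    kappa_x_mean: float = 0.15
    kappa_x_sd: float = 0.10
    kappa_y_mean: float = 0.00
    kappa_y_sd: float = 0.12
    kappa_rho_hpx: float = -0.253
    kappa_rho_hpy: float = -0.435
    od_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise ConfigurationError("n_eyes must be >= 1")
        for name in (
            "hole_x_mag_sd", "hole_y_mag_sd", "pupil_x_mag_sd", "pupil_y_mag_sd",
            "wtw_sd", "corneal_vertical_sd", "pupil_diam_h_sd", "pupil_diam_v_sd",
            "kappa_x_sd", "kappa_y_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("hole_p_superior", "hole_p_nasal", "pupil_p_superior",
                     "pupil_p_nasal", "od_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("rho_x", "rho_y", "kappa_rho_hpx", "kappa_rho_hpy"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [-1, 1]")


@dataclass(frozen=True)
class EyeGeometry:
    """Ground-truth geometry of one implanted eye, in the anatomic frame.

    Offsets are signed (x, y) in mm relative to the corneal center, +x nasal
    and +y superior; OD/OS only affects how the eye is rasterized.
    """

    eye_id: str
    laterality: str  # "OD" | "OS"
    wtw_mm: float
    corneal_vertical_mm: float
    pupil_center_mm: tuple[float, float]
    pupil_diameters_mm: tuple[float, float]  # (horizontal, vertical)
    hole_center_mm: tuple[float, float]
    hole_diameter_um: float = HOLE_DIAMETER_UM
    kappa_offset_mm: tuple[float, float] = (float("nan"), float("nan"))

    def validate(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ConfigurationError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.hole_diameter_um != HOLE_DIAMETER_UM:
            raise ConfigurationError("hole_diameter_um is fixed at 360")
        if not _containment_ok(
            np.array([self.hole_center_mm[0]]), np.array([self.hole_center_mm[1]]),
            np.array([self.pupil_center_mm[0]]), np.array([self.pupil_center_mm[1]]),
            np.array([self.wtw_mm]), np.array([self.corneal_vertical_mm]),
            np.array([self.pupil_diameters_mm[0]]), np.array([self.pupil_diameters_mm[1]]),
        )[0]:
            raise ConfigurationError("geometry containment violated (pupil/hole vs cornea)")


@dataclass(frozen=True)
class RenderConfig:
    """Rasterization parameters for slit-lamp-like renders.

    Default scale of 48 um/px makes the 360-um hole 7.5 px across and a
    10.28-mm cornea ~214 px across, matching the hole-fixed normalization
    used when analyzing real photographs at 10x magnification.
    """

    scale_um_per_px: float = 48.0
    width: int = 320
    height: int = 320
    illumination_azimuth_deg: float = 180.0  # direction of the bright side
    illumination_gradient: float = 0.15      # relative edge-to-center modulation
    noise_sigma: float = 3.0                 # additive Gaussian, 8-bit units
    sclera_level: float = 220.0
    iris_level: float = 120.0
    pupil_level: float = 40.0
    ring_level: float = 200.0
    ring_width_px: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ConfigurationError("scale_um_per_px must be > 0")
        if self.width < 8 or self.height < 8:
            raise ConfigurationError("image dimensions too small")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class RenderRecord:
    """Sidecar ground truth for one render, pixel coordinates post-mirroring."""

    eye_id: str
    laterality: str
    scale_um_per_px: float
    wtw_mm: float
    limbus_center_px: tuple[float, float]
    pupil_center_px: tuple[float, float]
    hole_center_px: tuple[float, float]
    limbus_semi_axes_px: tuple[float, float]
    pupil_semi_axes_px: tuple[float, float]
    hole_diameter_px: float


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------


def _trunc_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Quantile of Normal(mean, sd) truncated at zero; degenerate when sd == 0."""
    if sd == 0:
        return np.full_like(u, mean)
    a = (0.0 - mean) / sd
    return sps.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _coupled_magnitudes(
    rng: np.random.Generator, n: int, rho_s: float,
    m1: float, s1: float, m2: float, s2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two zero-truncated-normal magnitude samples with Spearman coupling rho_s."""
    r = float(np.clip(spearman_to_pearson(rho_s), -0.999999, 0.999999))
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    u1, u2 = sps.norm.cdf(z1), sps.norm.cdf(z2)
    return _trunc_ppf(u1, m1, s1), _trunc_ppf(u2, m2, s2)


def _signs(rng: np.random.Generator, n: int, p_positive: float) -> np.ndarray:
    return np.where(rng.random(n) < p_positive, 1.0, -1.0)


def _containment_ok(xh, yh, xp, yp, wtw, cv, pdh, pdv) -> np.ndarray:
    """Vectorized geometry checks; conservative per-axis bounds."""
    hole_r = HOLE_DIAMETER_UM / 2000.0  # mm
    pupil_in_cornea = (np.abs(xp) + pdh / 2 < wtw / 2) & (np.abs(yp) + pdv / 2 < cv / 2)
    hole_in_cornea = (np.abs(xh) + hole_r < wtw / 2) & (np.abs(yh) + hole_r < cv / 2)
    d_hp = np.hypot(xh - xp, yh - yp)
    hole_in_pupil = d_hp + hole_r < np.minimum(pdh, pdv) / 2
    # WTW bounds match the calibration precondition downstream
    sane = (wtw >= 9.0) & (wtw <= 14.0) & (cv > 7.0) & (pdh > 1.0) & (pdv > 1.0)
    return pupil_in_cornea & hole_in_cornea & hole_in_pupil & sane


def _sample_block(rng: np.random.Generator, n: int, p: CohortParams) -> dict[str, np.ndarray]:
    xh_mag, xp_mag = _coupled_magnitudes(
        rng, n, p.rho_x, p.hole_x_mag_mean, p.hole_x_mag_sd,
        p.pupil_x_mag_mean, p.pupil_x_mag_sd)
    yh_mag, yp_mag = _coupled_magnitudes(
        rng, n, p.rho_y, p.hole_y_mag_mean, p.hole_y_mag_sd,
        p.pupil_y_mag_mean, p.pupil_y_mag_sd)
    xh = _signs(rng, n, p.hole_p_nasal) * xh_mag
    yh = _signs(rng, n, p.hole_p_superior) * yh_mag
    xp = _signs(rng, n, p.pupil_p_nasal) * xp_mag
    yp = _signs(rng, n, p.pupil_p_superior) * yp_mag
    wtw = rng.normal(p.wtw_mean, p.wtw_sd, n)
    cv = rng.normal(p.corneal_vertical_mean, p.corneal_vertical_sd, n)
    pdh = rng.normal(p.pupil_diam_h_mean, p.pupil_diam_h_sd, n)
    pdv = rng.normal(p.pupil_diam_v_mean, p.pupil_diam_v_sd, n)
    kx = _coupled_to(rng, xh - xp, p.kappa_rho_hpx, p.kappa_x_mean, p.kappa_x_sd)
    ky = _coupled_to(rng, yh - yp, p.kappa_rho_hpy, p.kappa_y_mean, p.kappa_y_sd)
    lat = np.where(rng.random(n) < p.od_fraction, "OD", "OS")
    return dict(xh=xh, yh=yh, xp=xp, yp=yp, wtw=wtw, cv=cv, pdh=pdh, pdv=pdv,
                kx=kx, ky=ky, lat=lat)


def _coupled_to(
    rng: np.random.Generator, anchor: np.ndarray, rho_s: float, mean: float, sd: float
) -> np.ndarray:
    """Normal sample rank-coupled (Gaussian copula) to an existing sample."""
    n = len(anchor)
    if n == 1:
        return np.array([rng.normal(mean, sd)]) if sd > 0 else np.array([mean])
    ranks = sps.rankdata(anchor, method="average")
    z_anchor = sps.norm.ppf((ranks - 0.5) / n)
    r = float(np.clip(spearman_to_pearson(rho_s), -0.999999, 0.999999))
    z = r * z_anchor + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return mean + sd * z


def sample_cohort(params: CohortParams, seed: int | None = None) -> list[EyeGeometry]:
    """Sample ``params.n_eyes`` ground-truth eye geometries.

    Reproducible for a fixed ``(params, seed)``; eyes violating the
    containment invariants are resampled, so the output never contains an
    invalid geometry.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_eyes
    block = _sample_block(rng, n, params)
    ok = _containment_ok(block["xh"], block["yh"], block["xp"], block["yp"],
                         block["wtw"], block["cv"], block["pdh"], block["pdv"])
    # Containment violations are resolved by redrawing the ocular dimensions
    # only, so the offset-magnitude marginals stay exactly as configured; if
    # an offset is too extreme for any plausible eye, the whole eye is
    # redrawn as a fallback.
    dim_keys = ("wtw", "cv", "pdh", "pdv")
    tries = 0
    while not ok.all():
        tries += 1
        if tries > 200:
            raise ConfigurationError(
                "could not satisfy geometry containment; parameters produce "
                "offsets incompatible with the pupil/cornea sizes")
        bad = np.where(~ok)[0]
        repl = _sample_block(rng, len(bad), params)
        keys = dim_keys if tries <= 50 else tuple(block)
        for key in keys:
            block[key][bad] = repl[key]
        ok = _containment_ok(block["xh"], block["yh"], block["xp"], block["yp"],
                             block["wtw"], block["cv"], block["pdh"], block["pdv"])
    eyes = []
    for i in range(n):
        eyes.append(EyeGeometry(
            eye_id=f"eye_{i:04d}",
            laterality=str(block["lat"][i]),
            wtw_mm=float(block["wtw"][i]),
            corneal_vertical_mm=float(block["cv"][i]),
            pupil_center_mm=(float(block["xp"][i]), float(block["yp"][i])),
            pupil_diameters_mm=(float(block["pdh"][i]), float(block["pdv"][i])),
            hole_center_mm=(float(block["xh"][i]), float(block["yh"][i])),
            kappa_offset_mm=(float(block["kx"][i]), float(block["ky"][i])),
        ))
    return eyes


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _ellipse_coverage(xx, yy, cx, cy, ax, ay) -> np.ndarray:
    """Anti-aliased interior coverage of an axis-aligned ellipse (~1 px edge)."""
    rho = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    # approximate signed pixel distance to the boundary
    grad = np.sqrt(((xx - cx) / ax**2) ** 2 + ((yy - cy) / ay**2) ** 2) / np.maximum(rho, 1e-9)
    dist = (rho - 1.0) / np.maximum(grad, 1e-9)
    return np.clip(0.5 - dist, 0.0, 1.0)


def _ring_coverage(xx, yy, cx, cy, radius, width) -> np.ndarray:
    r = np.hypot(xx - cx, yy - cy)
    return np.clip(width / 2.0 - np.abs(r - radius) + 0.5, 0.0, 1.0)


def mirror_image(image: np.ndarray, laterality: str) -> np.ndarray:
    """Horizontal flip for left (OS) eyes; identity for right (OD) eyes."""
    if laterality == "OD":
        return image
    if laterality == "OS":
        return np.ascontiguousarray(image[:, ::-1])
    raise ConfigurationError(f"laterality must be OD or OS, got {laterality!r}")


def render_eye(geom: EyeGeometry, cfg: RenderConfig | None = None) -> tuple[np.ndarray, RenderRecord]:
    """Rasterize one eye as an 8-bit grayscale image plus ground-truth sidecar.

    The eye is drawn in a right-eye raster convention (raster +x = nasal,
    raster +y = inferior) with the limbus centered in the frame; OS eyes are
    then mirrored horizontally, as they would appear when photographed.
    Structures get flat intensity levels with ~1 px anti-aliased edges, a
    multiplicative linear illumination gradient emulating diffuse oblique
    slit-lamp light, and additive Gaussian noise.
    """
    cfg = cfg or RenderConfig()
    cfg.validate()
    geom.validate()
    ppm = 1000.0 / cfg.scale_um_per_px  # px per mm
    w, h = cfg.width, cfg.height
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0

    lim_ax, lim_ay = geom.wtw_mm / 2 * ppm, geom.corneal_vertical_mm / 2 * ppm
    if cx0 - lim_ax < 1 or cx0 + lim_ax > w - 2 or cy0 - lim_ay < 1 or cy0 + lim_ay > h - 2:
        raise RenderError(
            f"limbus ellipse ({2*lim_ax:.0f} x {2*lim_ay:.0f} px) exceeds the "
            f"{w} x {h} frame")

    # anatomic mm -> OD raster px (+x nasal -> right, +y superior -> up)
    def to_px(xy_mm):
        return cx0 + xy_mm[0] * ppm, cy0 - xy_mm[1] * ppm

    pup_cx, pup_cy = to_px(geom.pupil_center_mm)
    hol_cx, hol_cy = to_px(geom.hole_center_mm)
    pup_ax = geom.pupil_diameters_mm[0] / 2 * ppm
    pup_ay = geom.pupil_diameters_mm[1] / 2 * ppm
    hole_d_px = geom.hole_diameter_um / cfg.scale_um_per_px

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), cfg.sclera_level)
    a_lim = _ellipse_coverage(xx, yy, cx0, cy0, lim_ax, lim_ay)
    img = img * (1 - a_lim) + cfg.iris_level * a_lim
    a_pup = _ellipse_coverage(xx, yy, pup_cx, pup_cy, pup_ax, pup_ay)
    img = img * (1 - a_pup) + cfg.pupil_level * a_pup
    a_ring = _ring_coverage(xx, yy, hol_cx, hol_cy, hole_d_px / 2, cfg.ring_width_px)
    img = img * (1 - a_ring) + cfg.ring_level * a_ring

    if cfg.illumination_gradient != 0:
        az = np.deg2rad(cfg.illumination_azimuth_deg)
        t = ((xx - cx0) * np.cos(az) + (yy - cy0) * np.sin(az)) / max(w, h)
        img = img * (1.0 + cfg.illumination_gradient * t)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if geom.laterality == "OS":
        img = mirror_image(img, "OS")
        flip = lambda xy: ((w - 1) - xy[0], xy[1])  # noqa: E731
        lim_c, pup_c, hol_c = flip((cx0, cy0)), flip((pup_cx, pup_cy)), flip((hol_cx, hol_cy))
    else:
        lim_c, pup_c, hol_c = (cx0, cy0), (pup_cx, pup_cy), (hol_cx, hol_cy)

    record = RenderRecord(
        eye_id=geom.eye_id,
        laterality=geom.laterality,
        scale_um_per_px=cfg.scale_um_per_px,
        wtw_mm=geom.wtw_mm,
        limbus_center_px=lim_c,
        pupil_center_px=pup_c,
        hole_center_px=hol_c,
        limbus_semi_axes_px=(lim_ax, lim_ay),
        pupil_semi_axes_px=(pup_ax, pup_ay),
        hole_diameter_px=hole_d_px,
    )
    return img, record


def geometry_fields() -> list[str]:
    """Column order used by the cohort CSV writer."""
    return [
        "eye_id", "laterality", "wtw_mm", "corneal_vertical_mm",
        "cx_pupil_mm", "cy_pupil_mm", "pupil_diam_h_mm", "pupil_diam_v_mm",
        "cx_hole_mm", "cy_hole_mm", "hole_diameter_um", "kappa_x_mm", "kappa_y_mm",
    ]


def geometry_to_row(g: EyeGeometry) -> dict:
    return {
        "eye_id": g.eye_id,
        "laterality": g.laterality,
        "wtw_mm": g.wtw_mm,
        "corneal_vertical_mm": g.corneal_vertical_mm,
        "cx_pupil_mm": g.pupil_center_mm[0],
        "cy_pupil_mm": g.pupil_center_mm[1],
        "pupil_diam_h_mm": g.pupil_diameters_mm[0],
        "pupil_diam_v_mm": g.pupil_diameters_mm[1],
        "cx_hole_mm": g.hole_center_mm[0],
        "cy_hole_mm": g.hole_center_mm[1],
        "hole_diameter_um": g.hole_diameter_um,
        "kappa_x_mm": g.kappa_offset_mm[0],
        "kappa_y_mm": g.kappa_offset_mm[1],
    }


def geometry_from_row(row: dict) -> EyeGeometry:
    return EyeGeometry(
        eye_id=str(row["eye_id"]),
        laterality=str(row["laterality"]),
        wtw_mm=float(row["wtw_mm"]),
        corneal_vertical_mm=float(row["corneal_vertical_mm"]),
        pupil_center_mm=(float(row["cx_pupil_mm"]), float(row["cy_pupil_mm"])),
        pupil_diameters_mm=(float(row["pupil_diam_h_mm"]), float(row["pupil_diam_v_mm"])),
        hole_center_mm=(float(row["cx_hole_mm"]), float(row["cy_hole_mm"])),
        hole_diameter_um=float(row["hole_diameter_um"]),
        kappa_offset_mm=(float(row["kappa_x_mm"]), float(row["kappa_y_mm"])),
    )
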