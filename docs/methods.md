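# Methods

This note documents the models, numerical choices, and limitations behind
`iclcentration`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what the code verifies.

## The measurement model

A slit-lamp photograph of an implanted eye shows three nested quasi-
elliptical structures: the corneo-scleral boundary (limbus), the pupil, and
the bright ring of the lens's 360-μm central perforation. The quantity of
interest is the 2-D offset of the hole center and the pupil center from the
corneal center, in millimetres, in an anatomic frame that pools right and
left eyes.

**Center definition.** Clinically, each structure's center is defined as
the intersection of its longest horizontal and vertical diameters. For any
ellipse this intersection coincides with the algebraic (conic) center: the
squared length of the horizontal chord at height *y* is the discriminant of
the conic restricted to that row — a concave quadratic in *y* whose vertex
is the center's *y*-coordinate, and symmetrically for vertical chords. The
test suite verifies the equivalence to ≤ 1e-9 px on 100 random ellipses
against a brute-force chord scan, which licenses using the fitted ellipse
center everywhere.

**Calibration.** Pixels convert to millimetres through the white-to-white
(WTW) magnification mm/px = WTW / (horizontal limbus diameter in pixels),
with WTW supplied per eye from biometry metadata; no attempt is made to
infer WTW from the image. A hole-fixed normalization (resize so the 360-μm
ring spans 7.5 px, i.e. 48 μm/px) is retained only as the optional
`--normalize-hole` preprocessing flag: composed with the WTW magnification
it yields the same millimetre values, so the pipeline collapses the two
scalings into one conversion. The horizontal limbus diameter is the
ellipse's x-extent, 2√(a²cos²θ + b²sin²θ), which equals its longest
horizontal chord.

**Anatomic frame.** Origin at the corneal center; raster *y* is negated so
+y is superior; OS (left-eye) *x*-offsets are negated so +x is nasal for
both lateralities. Distances are D = √(x² + y²); component magnitudes are
absolute values of the signed components; the hole-minus-pupil vector keeps
its signs (the kappa correlations are only interpretable with signs).
Quadrant labels read the signs, with exact-zero components assigned
deterministically to superior/nasal and flagged as boundary cases — a
zero-measure event on measured data that keeps tabulations reproducible.

## Segmentation

All detectors share three numerical choices:

- **Illumination flattening.** The oblique diffuse illumination is modeled
  as a multiplicative linear gradient; a least-squares plane fit to the
  intensity field is divided out before thresholding. Thresholds are then
  3-class Otsu (pupil / iris / sclera).
- **Sub-pixel boundaries.** Region masks only seed the search; the fitted
  boundary is the closed iso-contour (linear-interpolation marching
  squares) at the level midway between the two adjacent intensity medians.
  This matters most for the hole, whose ring is only ~7.5 px across.
- **Direct least-squares ellipse fit.** The constrained conic fit
  (4AC − B² > 0) in the numerically stable Halir–Flusser block form, with
  points pre-conditioned to zero mean and unit RMS radius. Residuals are
  Sampson distances. On exact samples the construction parameters are
  recovered to ~1e-6 px.

Structure-specific choices: the limbus contour is fitted by RANSAC
(default 100 iterations, 1-px inlier tolerance, seeded) because gradient
residuals bias a fraction of its edge points; pupil and hole contours are
high-contrast and use direct fits. The hole detector searches bright
components inside the pupil, traces both ring edges and averages their
fits (ring centerline); when one edge merges into the iris — the hole near
the pupil margin — the remaining contour still centers the ring and the
diameter is estimated from the intensity-weighted mean crest radius.
Candidates must lie within 20% of the calibrated 360-μm prior; among
multiple candidates the one closest to the prior wins. Detection failures
raise typed errors with diagnostics rather than returning degenerate fits.

Measured recovery on synthetic renders (seeded, default noise): median
center error ≲ 0.06 px for all three structures, 95th percentile well
under 1.5 px; end-to-end mean absolute error of Ð(H−C) ≈ 0.002 mm over a
200-eye rendered cohort (test threshold 0.03 mm).

## Synthetic cohorts

The generator emulates the study conditions of an 89-eye post-implantation
series and is the source of all test fixtures.

- **Component magnitudes** are zero-truncated normals with defaults equal
  to the published cohort moments: hole-vs-corneal-center 0.16 ± 0.12 mm
  (x) and 0.30 ± 0.19 mm (y); pupil-vs-corneal-center 0.28 ± 0.19 mm and
  0.27 ± 0.14 mm. The mean/SD parameterize the *untruncated* normal;
  truncation shifts realized means slightly upward (e.g. 0.182 for the
  hole x-magnitude), which the tests check against the closed-form
  truncated-normal expectation within 3 standard errors.
- **Signs** are Bernoulli: the hole is superior with p = 0.955 and nasal
  with p = 0.506 (near-even horizontal split); the pupil is superonasal
  with p = 0.955 on both axes, matching the published quadrant counts.
- **Hole/pupil coupling** uses a Gaussian copula targeting Spearman 0.57
  (x) and 0.42 (y) — the published rank correlations — via the exact
  bivariate-normal relation r = 2 sin(πρ_s/6).
- **Kappa offsets** (pupil offset from the corneal vertex) are normal,
  K-x 0.15 ± 0.10 mm and K-y 0.00 ± 0.12 mm — plausible biometry values,
  chosen once since no marginals are published — and rank-coupled to the
  signed hole-minus-pupil components with default targets −0.253 (x) and
  −0.435 (y), the published correlations.
- **Ocular dimensions** derive from the published pixel statistics at the
  48 μm/px hole-fixed scale: WTW 10.28 ± 0.70 mm, vertical cornea
  9.69 ± 0.59 mm, pupil 2.54 ± 0.57 × 2.43 ± 0.56 mm.
- **Containment** (pupil strictly inside cornea; hole inside cornea and
  fully inside the pupil, without which a rendered fixture would be
  undetectable by construction) is enforced by resampling — the ocular
  dimensions only, so the offset marginals stay exactly as configured,
  with whole-eye redraw as a fallback for unservable offsets. Eyes are
  treated as independent units.

**Rendering** draws flat intensity levels (sclera 220, iris 120, pupil 40,
ring 200 on the 8-bit scale) with ~1-px anti-aliased edges, the ring at
the hole diameter (7.5 px at the default 48 μm/px), a multiplicative
linear gradient emulating the 60°-temporal diffuse illumination, and
additive Gaussian noise (default σ = 3). Eyes are drawn in a right-eye
raster convention and OS eyes mirrored horizontally, so an OS render is
pixel-identical to the flipped OD render of the same geometry.

What the renders do **not** emulate: iris texture, corneal and Purkinje
reflections, eyelids/lashes, defocus, pupil dynamics, or rotated corneal
ellipses. Passing tests therefore demonstrate correctness of the geometry,
calibration, and statistics chain and robustness to gradient + Gaussian
noise — not clinical-grade segmentation of real photographs, where manual
annotation quality is the unknown.

## Statistics

- Mean ± sample SD (n−1); quadrant percentages rounded half-away-from-zero
  to 2 decimals and recomputable from the integer counts.
- **Wilcoxon signed-rank** (two-sided, paired): zero differences dropped;
  exact null distribution for ≤ 25 nonzero pairs, computed by dynamic
  programming over doubled midranks (so ties are handled exactly; the
  distribution is symmetric because each sign assignment pairs with its
  complement); normal approximation with tie and continuity corrections
  above. The exact path is verified against exhaustive 2ⁿ sign enumeration
  for n ≤ 10 and against scipy on tie-free fixtures.
- **Spearman** via average ranks with the t-approximation p, verified to
  1e-12 against Pearson-on-average-ranks.
- All p's are two-sided and unadjusted, reported to 3 decimals with
  "< 0.001" below that.
- Cohorts of n < 5 carry summary statistics but flag the tests
  unavailable; an all-zero-difference Wilcoxon reports p = 1 with a flag.

## Problem sizes

The shipped checks use 10,000 sampled eyes for distribution-level
statistics, 100 × 89 eyes for the significance replication, 200 rendered
eyes for end-to-end recovery, and 30–50 rendered eyes for the seeded
robustness sweeps — sizes at which every Monte-Carlo criterion is stable
across seeds while the whole suite runs in about a minute.

## Known limitations

- The published component values are interpreted as unsigned magnitudes
  (their near-even nasal/temporal split makes signed means implausible);
  within-vector x/y independence is assumed, as the joint distribution is
  unreported.
- The WTW magnification treats the limbus as the corneal outline; parallax
  between the iris plane and the lens plane is not modeled (the
  measurement is a 2-D projection).
- The kappa marginals are package choices, not published values; only the
  kappa rank couplings are anchored to published correlations.
- Automated detection is validated against synthetic ground truth only; no
  claim is made that it matches human annotation of real slit-lamp images.
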