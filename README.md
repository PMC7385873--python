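# iclcentration

Centration analysis of the EVO-ICL central hole in anterior-segment eye
images.

The EVO implantable collamer lens (EVO-ICL), a posterior-chamber phakic
lens used to correct moderate-to-high myopia, carries a 360-μm perforation
at its optic center. Because the hole is directly visible in a slit-lamp
photograph, its position is a non-invasive proxy for the position of the
implanted lens. This package measures where that hole sits relative to two
anatomic references — the **corneal center** C\_C (center of the fitted
limbus ellipse, equivalently the intersection of its longest horizontal and
vertical diameters) and the **pupil center** C\_P (same construction on the
pupil ellipse) — and aggregates per-eye offsets into cohort statistics.

It is aimed at ophthalmic-imaging researchers who want a reproducible,
testable version of this measurement chain: every stage can be exercised on
synthetic slit-lamp-like renders with known ground truth.

## Method

For each eye the pipeline:

1. **Segments** the limbus, pupil, and central-hole ring as ellipses.
   Boundaries are localized at sub-pixel precision on iso-contours of the
   illumination-flattened image and fitted with the direct least-squares
   conic fit (Fitzgibbon/Halir–Flusser); the limbus fit is wrapped in
   random-sample consensus to resist the oblique illumination gradient.
2. **Calibrates** pixels to millimetres with the white-to-white (WTW)
   magnification, mm/px = WTW / (horizontal limbus diameter in px), the WTW
   being the biometer-measured horizontal corneal diameter.
3. **Converts** centers to the anatomic frame: origin at C\_C, +x nasal,
   +y superior; left-eye (OS) x-offsets are negated so both eyes pool on a
   common nasal/temporal axis.
4. **Derives**, per eye, the distances Ð(H−C), Ð(P−C), Ð(H−P) via
   D = √(x² + y²), the component magnitudes ÐHx, ÐHy, ÐPx, ÐPy, the signed
   hole-minus-pupil components ÐHPx, ÐHPy, and quadrant labels
   (superior/inferior × nasal/temporal).
5. **Aggregates** a cohort: mean ± SD per metric, quadrant count/percentage
   tables, two-sided paired Wilcoxon signed-rank tests (Ð(H−C) vs Ð(P−C),
   ÐHx vs ÐPx, ÐHy vs ÐPy), and Spearman correlations, including between
   the kappa-angle pupil offsets (K-x, K-y) and the hole-position metrics.

A first-class synthetic-data module samples ground-truth eye geometries
from configurable distributions (component magnitudes from zero-truncated
normals, hole/pupil magnitudes coupled through a Gaussian copula to target
Spearman rank correlations) and renders them as 8-bit grayscale images with
a ground-truth sidecar.

## Worked example

```python
import dataclasses
from iclcentration import (CohortParams, RenderConfig, sample_cohort,
                           render_eye, process_eye, summarize)

eyes = sample_cohort(CohortParams(n_eyes=89), seed=1)
records = []
for i, geom in enumerate(eyes):
    image, truth = render_eye(geom, dataclasses.replace(RenderConfig(), seed=i))
    records.append(process_eye(image, wtw_mm=geom.wtw_mm,
                               laterality=geom.laterality, eye_id=geom.eye_id,
                               kappa_offset_mm=geom.kappa_offset_mm))
s = summarize(records)
m = s.metrics
print(f"D(H-C) = {m['d_hc_mm']['mean']:.2f} +/- {m['d_hc_mm']['sd']:.2f} mm")
print(f"D(P-C) = {m['d_pc_mm']['mean']:.2f} +/- {m['d_pc_mm']['sd']:.2f} mm")
print(f"Wilcoxon DHx vs DPx: p = {s.wilcoxon['dhx_vs_dpx'].p_value:.2e}")
print(f"hole superior-nasal: {s.quadrants['hole_vs_cornea']['superior-nasal']['percent']}%")
```

prints

```
D(H-C) = 0.36 +/- 0.15 mm
D(P-C) = 0.41 +/- 0.13 mm
Wilcoxon DHx vs DPx: p = 1.79e-11
hole superior-nasal: 53.93%
```

i.e. on this simulated 89-eye cohort the hole sits on average 0.36 mm from
the corneal center — closer than the pupil center (0.41 mm) — and its
horizontal offset is significantly smaller than the pupil's, the pattern of
clinical interest. Segmentation runs on the rendered images, not on the
ground truth, so these numbers include the full measurement chain.

The same workflow is available from the shell:

```
iclcentration simulate --out run/ --seed 1 -n 89
iclcentration measure  --in run/ --out run/records.csv
iclcentration report   --records run/records.csv --out run/
```

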