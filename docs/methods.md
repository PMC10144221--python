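# Methods

This note documents the models, algorithms, parameter defaults, and known
limitations of the `printability` package, and what the synthetic-data tests
do and do not demonstrate about real printed structures.

## Rheology and pressure planning

The flow curve of an alginate/GelMA ink shows a Newtonian plateau at low
shear and a shear-thinning regime above roughly 1 1/s. Only the
shear-thinning regime is described by the Ostwald–de Waele model
η = K·γ̇^(n−1); the default fit window therefore starts at 1 1/s, and the
window is a user parameter because the plateau edge varies between
formulations. The fit is ordinary least squares in log–log space (the model
is exactly linear there: slope n−1, intercept log K), the universal practice
for power-law fits; the coefficient of determination of that regression is
reported as `fit_quality`. Replicate sweeps are pooled before fitting.

Pressure planning couples the power law with the Hagen–Poiseuille relation
for a cylindrical capillary and uses the exact closed-form inversion

    p = 2·K·l · ((3n+1)·v̄ / n)^n / R^(n+1)

rather than numerical root finding — the relation is analytically invertible
and the closed form is what the roundtrip and Newtonian-limit tests check to
1e−9 and 1e−12 relative, respectively.

Public interfaces use mm, s, kPa, and Pa·s^n; conversion to SI happens once,
inside `flow_rate`/`required_pressure`. The R^(n+1) term makes the formula
extremely sensitive to unit mistakes, which is why there is exactly one
conversion layer.

Note on the reference operating points: with the rounded fitted parameters
n = 0.35, K = 146.39 of the lighter ink, the closed form gives ≈ 76.8 kPa,
not the 80.5 kPa quoted alongside those parameters in the source protocol —
the quoted pressure was evidently computed from unrounded fit parameters.
The package does not force agreement; the value computed from the printed
parameters is the correct output of the formula. The denser ink's operating
point (n = 0.32, K = 284.09 → 129.1 kPa at 10 mm/s) is self-consistent and
is the package's reference check.

## Image processing

Photographs are a bright strand on a dark stage, acquired with a calibrated
monochrome camera (52 px/mm default). Processing:

1. **3×3 median pre-filter** (edge-replicated) to remove shot noise without
   moving edges. The median size is a parameter; 3 is the default.
2. **Local-mean thresholding**: foreground iff intensity > local mean +
   offset. The window defaults to ~3.2 expected strand widths in pixels
   (101 px for a 0.61 mm strand at 52 px/mm) and scales with the pixel
   pitch, which is what makes the metrics resolution-independent. Local
   (rather than global) thresholding makes the mask invariant to global
   intensity shifts and robust to the slow illumination gradients that ring
   lights produce.
3. **Automatic offset**: near the edge of a strand that spans a fraction
   f of the window, the local mean sits about f·C above background, where C
   is the strand/background contrast (estimated as the difference of class
   medians of an Otsu split). The offset (0.5 − f)·C therefore places the
   effective threshold at the half-intensity level of the blurred edge, where
   the binary boundary coincides with the true strand boundary. The offset is
   computed in two passes — detect with the nominal strand size, re-estimate
   the actual strand width from the mask (mean distance-to-background of a
   constant-width strand is width/4), re-threshold — so strands wider or
   narrower than the nozzle are still measured without bias. A fixed offset
   remains available as an override. With an offset of 0 (threshold exactly
   at the local mean) half of all pure-background pixels would binarize as
   foreground under any noise, which is why a positive, contrast-derived
   offset is the default.
4. **Segmentation**: 8-connected labeling; components below 0.2 mm² are
   discarded as debris (small enough to keep thin strand fragments, large
   enough to drop specks). Outer and interior-hole boundaries are traced at
   the half-pixel contour level (marching squares), giving sub-pixel
   polylines; at 52 px/mm a strand is only ~32 px wide, and integer-pixel
   boundaries would quantize widths by ~3%.

Coordinates: pixel centers at integer (row, col); physical x = col/px_per_mm
rightward, y = row/px_per_mm downward; all metric outputs in mm.

## Geometry metrics

**Line.** The principal axis of the largest component defines the line
direction; components whose centroid lies within 3 nozzle diameters of that
axis count as line segments (`segment_count`, `interrupted`). Width is the
mean foreground pixel count per 1-px cross-section bin over the middle third
of the designed length. Length is material-covered: per segment, the axis
extent minus one strand width, which removes the two round end caps, so an
ideal 30 mm print scores l_n = 1 and a line with a gap scores the covered
fraction — values below 1 mean missing material.

**Circle.** The largest component must be annular. Geometric
(orthogonal-distance) least-squares circles — algebraic Kasa initialization
refined by Levenberg–Marquardt — are fitted to the hole boundary (r_i) and
the outer boundary (r_o); geometric rather than algebraic fitting keeps the
estimate stable on partial arcs. The start marker is the non-annular
component closest in size to the designed 3 mm marker; the strand width is
the mean outer-minus-inner boundary radius along rays over a 7.2° arc (2% of
the circumference) diametrically opposite the marker. For any symmetric
stroke, (r_i + r_o)/2 equals the midline radius exactly, which is the
identity the circle tests verify to ±0.002.

**Angle composite.** The centerline is the longest path of the skeleton
(which drops cap and corner spurs); corners come from Ramer–Douglas–Peucker
simplification, then each corner is refined by intersecting total-least-
squares line fits to the skeleton points of its two arms, because the raw
simplification vertex sits on the rounded skeleton apex and is pulled toward
the concave side. Inner and outer corner angles are measured by TLS line
fits to boundary points of the two arms, with iterative outlier trimming
(2.5 robust SDs, two rounds). The apex exclusion is side-specific: the outer
fit window starts just beyond the round join (w/2 plus half a nozzle
diameter from the corner); the inner fit window starts 1.5 nozzle diameters
beyond the inner boundary's own apex, which sits (w/2)/sin(α/2) from the
centerline corner — for a 30° corner that is nearly two nozzle diameters
out, and optical blur fills the narrow wedge just beyond it, so a fixed
exclusion measured from the corner would let the filled region tilt the fit.
Both windows span four nozzle diameters. Widths are probed at five points
along the centerline, clear of corners and ends, by perpendicular
cross-sections restricted to the contiguous foreground run around the
centerline (so a cut inside a narrow wedge cannot pick up the neighboring
arm).

The structure's pose is always estimated from the data (principal axis,
fitted center + marker, skeleton ordering); no fiducials are assumed, and
the designed-angle ordering is matched forward or reversed, whichever agrees
better with the measured centerline angles.

## Synthetic data

`render_structure` draws the CAD path (line 30 mm; circle radius 15 mm with
a 3 mm start marker; 30/45/60° composite with 10 mm arms) as a
constant-width stroke with round caps and joins via an exact distance field,
converts distance to area-coverage alpha over one pixel (anti-aliasing, so
edges are non-binary like real photographs), then applies Gaussian blur
(default 0.05 mm), a linear illumination gradient (default 20 intensity
units across the frame), and additive Gaussian noise (default sd 5 on
levels of 20 background / 200 foreground). Gaps cut arc-length windows out
of the path; bulges add discs. Everything is deterministic per seed and
ships with a ground-truth sidecar.

What the renderer does **not** emulate: die swell and spreading (real
strands are wider than the nozzle for physical reasons — here stroke width
is simply a parameter), non-Gaussian optics, specular reflections from wet
hydrogel, translucency of the ink, and perspective/lens distortion. Passing
recovery tests therefore shows the measurement chain is unbiased on
well-formed images of known geometry; it does not certify performance on
poorly lit or translucent prints.

`simulate_viscosity` samples log-spaced sweeps (default 30 points over
0.1–1000 1/s) with unit-mean multiplicative lognormal noise (default CV 5%,
nine replicates — three biological × three technical, as in the reference
protocol). It does not simulate the low-shear plateau, so fits over the full
range recover the truth; real data require the fit window.

`simulate_cytometry` draws four lognormal clusters in (FSC, SSC, green,
red): live (green-dominant), dead (red-dominant), debris (low scatter),
agglomerates (very high scatter), with documented medians/CVs
(`CYTO_CLUSTERS`) chosen to give the cleanly separated populations a
properly stained calcein/PI sample shows; cluster overlap, spillover, and
doublet smearing are not modeled, so classification accuracy on simulated
data (≥99%) is an upper bound.

## Cytometry gating

Rectangular scatter gate plus per-channel thresholds (a stated
simplification of freehand gating). Defaults are on the simulation's
instrument-like scale (FSC 1e4–1.5e5); a percentile-based constructor
(1st–99th of the sample's own scatter) is available when no instrument
calibration exists. The red (dead) threshold is derived from a fixed-and-
permeabilized all-dead control as its 1st percentile after scatter gating,
so ≥99% of known-dead events classify as dead. Double-positive events count
as dead (PI entry indicates a compromised membrane) — configurable;
double-negative events are excluded from the viability denominator.
Compensation/spillover correction is omitted, as none is reported for the
calcein/PI pair. FCS support covers the plain list-mode linear float/double
subset of FCS 3.0/3.1, plus a CSV fallback (`fsc,ssc,green,red`).

## Statistics

Per formulation × metric: mean, sd, n, Jarque–Bera normality p-value
(α = 0.05). Between formulations: one-way ANOVA plus Tukey HSD pairwise
p-values, flagged significant at p < 0.05, all via scipy implementations —
these are standard tests, not re-derived. No multiple-testing correction is
applied across metrics (noted in the report footer). Uncertainty
propagation uses the first-order Taylor method for independent inputs,
σ_y = √Σ(cᵢσᵢ)²; the normalized metrics are linear in their measured
inputs, so the first-order result is exact for them, and the tests confirm
agreement with a 10⁵-draw Monte-Carlo oracle to 2%.

## Problem sizes and numerical choices

The test suite renders 20 randomized structures per kind at 52 px/mm
(strokes 0.45–1.05 mm, arbitrary rotation) for recovery checks, five
stroke widths for the circle identity, 200 simulated samples for viability
estimator calibration, and 1000 two-group repetitions for the type-I error
rate of the ANOVA path — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping Monte-Carlo error well below the tested
tolerances. Degenerate inputs are errors, not warnings: empty masks,
non-annular circles, corner-count mismatches, all-excluded gates, and
zero classified cells raise `ValueError` with a stable message.

## Known limitations

- Single-layer structures only; no 3-D or multi-layer reconstruction.
- No yield-stress/Herschel–Bulkley or viscoelastic rheology, wall slip, or
  temperature dependence; no shear-stress-based cell-damage prediction.
- The angle-measurement procedure (boundary-arm fits with apex exclusion)
  is a package design choice; no standard procedure exists in the field,
  and all window parameters are exposed for sensitivity analysis.
- Scatter gates are rectangles and fluorescence thresholds are scalars;
  curved or density-based gates are out of scope.
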