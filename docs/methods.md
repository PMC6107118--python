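# Methods

## The measurement problem

The head circumference (HC) of a fetus, measured on a transverse 2D
ultrasound plane, tracks gestational age (GA) and growth.  Clinically the
sonographer draws an ellipse around the outer edge of the skull; the HC is
that ellipse's perimeter in millimeters.  `fetalhc` automates the drawing:
given a grayscale frame and its physical pixel size, it returns a fitted
ellipse, the HC, and (via a growth chart) an estimated GA.

## Pipeline model

Each measurement *pipeline* is a fixed chain:

1. **Skull-likelihood map.**  Twelve Haar-like kernels (edge, line,
   center-surround and checkerboard families, upright and 45°-rotated) are
   evaluated at every pixel via integral images, at one or more physical
   scales.  Kernels are sized in mm, so a 7 mm kernel covers the same
   anatomy regardless of scanner zoom; responses are normalized to
   mean(+cells) − mean(−cells) so kernel pixel area drops out.  A random
   forest (10 trees, scikit-learn defaults otherwise) maps the feature
   vector to a soft vote in [0, 1].  Training positives are the pixels of
   the rasterized annotation ellipse; negatives are an equal number of
   pixels drawn uniformly at least `d_min` mm from the curve; each image
   also contributes its horizontal mirror (a flipped-transducer look).
2. **Center detection.**  Likelihood pixels above the 90th percentile vote
   in a circle-Hough accumulator (1 mm center grid, 1 mm radius steps,
   radii bounded by the pipeline's GA window through the growth chart:
   `r_min = BPD_P3(GA_min)/2`, `r_max = ceil(HC_P97/π − BPD_P97/2)` at
   `GA_max`).  The reported center is the vote-weighted centroid of
   accumulator cells within 80% of the peak: on an elliptical ring the
   single best circle osculates one end of the major axis and a plain
   argmax is biased by up to `a − b`, while the near-peak cells are
   symmetric about the true center (measured ≤ 1.4 mm error at speckle
   SNR ≈ 2, vs up to 7 mm for the argmax).
3. **Boundary tracing.**  The likelihood map is resampled to polar
   coordinates around the center (`N_angles` = 270 angles; radial step
   `S_dis` mm starting at the pipeline's radial offset, which hides small
   bright structures near the center).  Dynamic programming finds the
   exact minimal-cost left-to-right path (cost = 1 − likelihood, one
   radius per angle, |Δr| ≤ 1 sample, ties toward the smaller radius).
   Because the classifier lights the whole skull cross-section, this path
   follows the *midline* of the bone.  A second DP pass runs on the radial
   derivative of the raw image at native resolution, restricted to ±2 mm
   around the midline, and snaps the path to the strongest bright-to-dark
   outward transition — the outer table of the skull, which is what the
   clinical annotation protocol measures.  The stage-2 step bound is
   scaled to `ceil(S_dis / pixel_size)` samples so both stages allow the
   same radial speed in mm per angle step; a fixed 1-sample bound at
   native resolution could not track a band whose center moves by up to
   `S_dis` per angle.
4. **Ellipse fit and plausibility filter.**  Path points whose likelihood
   reaches the map-wide 95th percentile are kept (at least 6, the conic
   minimum) and fitted with the direct least-squares ellipse method
   (constrained conic `4AC − B² = 1`, stable block decomposition, inputs
   centered and scaled).  Fits with circumference below 38.6 mm — the
   smallest HC on the reference chart — are rejected as noise.

   The fifth-percentile rule can be read two ways: rank the path's own
   points and keep the top 5% (≈ 14 of 270), or keep the path points above
   the 95th percentile of the *map*.  The ranked reading concentrates the
   kept points on one short arc whenever the likelihood varies smoothly
   along the path, and a conic fit to a 14-point arc is ill-conditioned
   (we observed gross failures on phantoms).  The map-global reading keeps
   most on-skull points, because the skull occupies far less than 5% of
   the frame, and drops exactly the path excursions over background; it is
   the default (`mode="map"`), with the ranked rule available as
   `mode="rank"`.

## Multi-trimester systems and selection

First-trimester skulls are barely ossified and look nothing like
third-trimester ones, so one classifier for all of pregnancy is a
compromise.  System A uses one pipeline (all trimesters), system B two
(T1 | T2+T3), system C three (one per trimester).  Shipped parameters per
pipeline (GA windows at the clinical trimester cut-offs 14+0 and 28+0
weeks):

| system/pipeline | F_scales (mm) | d_min | r_min–r_max | S_dis | offset |
|---|---|---|---|---|---|
| A (all)  | 6, 20        | 0.0 | 5–61  | 0.4 | 0  |
| B-t1     | 2.5, 0.5, 11 | 0.2 | 5–18  | 0.2 | 0  |
| B-t23    | 7, 11        | 0.2 | 12–61 | 0.4 | 5  |
| C-t1     | 2.5, 0.5, 11 | 0.2 | 5–18  | 0.2 | 0  |
| C-t2     | 7            | 0.1 | 12–50 | 0.3 | 5  |
| C-t3     | 9, 12        | 0.1 | 34–61 | 0.5 | 10 |

All pipelines use 10 trees and 270 polar angles.  At measurement time all
pipelines run and the accepted candidate whose *stage-1 DP path* has the
highest median value on its own classifier's likelihood map wins (ties →
lower trimester).  Scoring the path rather than the fitted ellipse
boundary is deliberate: both traces lie on the same anatomy, but the path
score rewards the classifier that actually drove the extraction, and on
phantoms it separates the trimester-matched pipeline far more reliably
(19/20 matched vs 13/20 with ellipse-boundary scoring; the measured HC was
essentially identical either way).  `run_pipeline(..., score_on="ellipse")`
restores the other reading.

## Growth chart and GA estimation

Radius bounds, the plausibility floor and GA estimation all read a
GA-vs-percentile table (`ga_days, hc_p3, hc_p50, hc_p97, bpd_p3, bpd_p50,
bpd_p97`; GA strictly increasing, every column invertible).  Published
clinical charts are licensed tables the user supplies as CSV.
`fetalhc.growth.synthetic_growth_curve()` provides a synthetic stand-in
with clinical magnitudes — median HC rising from ≈ 39 mm at 9 weeks to
≈ 345 mm at term on a smooth quadratic in gestational weeks, BPD at 28.5%
of HC, ±7% P3/P97 envelopes — used by the test suite and the phantom
generator.  It is not a clinical reference and must not be used for
diagnosis.  GA is estimated by monotone linear interpolation of the P50
track; values outside the chart raise rather than extrapolate.

## Phantom generator

`fetalhc.phantom` renders fetal-head look-alikes so the entire chain can be
trained and evaluated without clinical data: a bright elliptical annulus
(ground truth = its outer edge) over darker brain/background, multiplied by
fully-developed speckle (squared magnitude of a smoothed complex Gaussian
field; at the default weight 0.5 the interior SNR is ≈ 2), with optional
acoustic shadow sectors that attenuate and break the ring, a fan-shaped
field of view, a midline echo, and bright distractor blobs.  Trimester
drives head size (HC ≈ 48–100 / 120–250 / 258–330 mm), pixel size within
the clinical 0.052–0.326 mm range, skull thickness (1.2 / 2.2 / 3.0 mm)
and ring contrast (first-trimester rings are rendered at 35% contrast,
mirroring pre-ossification skulls).  When a requested frame is too small
for a drawn head, the pixel size is raised within the clinical range and
the head shrunk until it fits — so small test frames cap third-trimester
HC near 300 mm.  Rendering is bit-reproducible from the spec's seed.

What the phantoms do *not* model: beam-angle-dependent bone response,
reverberation, real tissue texture inside the head, non-elliptical skulls,
and inter-observer annotation variability (phantom annotations are exact).
Passing the phantom suite therefore demonstrates the geometry and
signal-processing chain, not clinical-grade accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script render phantoms at 360 × 480 px
(clinical frames are 800 × 540), train system C on 18 phantoms (6 per
trimester) and evaluate on 20 held-out mixed-trimester phantoms; these
sizes are the package's chosen defaults for its own verification runs.
Determinism: every random draw flows from explicit integer seeds; DP and
point-selection ties break toward the smaller radius / angle index; the
Hough accumulator is rounded to 6 decimals before comparisons so FFT
round-off cannot flip a tie.  Ellipse perimeters use the complete elliptic
integral (machine precision at any aspect ratio).  Degenerate inputs
(blank images, collinear fit points, centers outside the frame, bands
outside the image) surface as recorded per-candidate failures at the
system level, never exceptions.

## Known limitations

* The pixel classifier is a *boundary* detector here: positives are the
  1-px annotation curve and negatives may legitimately fall mid-ring
  (`d_min` is 0.1–0.2 mm), so mid-bone pixels score lower than bone edges.
  The downstream stages only need the boundary lit, but the likelihood map
  should not be read as a bone-probability map.
* Standard-plane detection is out of scope: the input frame is assumed to
  be a valid transverse HC plane.
* One head per frame; non-isotropic pixels and 3D volumes are unsupported.
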