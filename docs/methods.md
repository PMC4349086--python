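# Methods

`flywalk` measures morphometric traits of single walking *Drosophila*
from two-channel video and ranks flies for selection experiments.  This
note documents the model behind each stage, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Imaging model

Each fly is recorded as a short sequence of registered two-channel
frames plus a fly-free background image:

* **blue channel** — backlight through a diffuser: the body appears as
  an opaque dark silhouette, the wing blades as semi-transparent grey,
  and veins/bristles as thin darker curves; legs are thin dark lines
  that move between frames;
* **red channel** — lateral transillumination: the body itself glows
  (the abdomen carrying a sex-dependent axial luminance pattern), the
  ocelli are bright dots, the compound eyes dark, and wing veins are
  visible as dark lines wherever the wing overlaps the glowing body.
  Off the body the red channel is dark.

All geometry is processed in pixels; `mm_per_px` (default 0.0087,
~115 px/mm, a plausible scale for a few-megapixel sensor imaging a
narrow tunnel) is applied only when reporting.

## Frame validation

Six per-frame criteria decide whether a frame is usable; a fly is
accepted when at least `qc.min_valid_frames = 3` frames pass all six.
The criteria are named in the imaging protocol; the operators and
thresholds are this package's choices, calibrated once on generator
output and fixed:

| check | operator | default threshold |
|---|---|---|
| focus | variance of Laplacian in the fly bounding box | ≥ 100 |
| border | no foreground pixel within `border_margin` px of an edge | 2 px |
| reflections | saturated (≥250) red pixels in the wing region | < 0.5 % |
| orientation | wing-blade area / body-core area (dorsal view shows both wings) | ≥ 0.3 |
| alignment | body-core principal axis vs tunnel axis | ≤ 10° |
| symmetry | IoU of silhouette with its mirror across its own axis | ≥ 0.85 |

Two details matter in practice.  The alignment angle is measured on the
dark body core only, because an asymmetric wing posture would otherwise
rotate the apparent body axis and a wing problem would masquerade as a
yaw problem.  The symmetry check first strips thin structures (legs)
with a morphological opening: leg placement is asymmetric in any single
walking frame and says nothing about wing or body symmetry.

## Body segmentation

Valid blue frames are background-subtracted, inverted (dark fly on a
bright field), and aligned by central image moments: centroid to image
centre, principal axis vertical.  The 180° ambiguity is resolved by
putting the heavier mass half (abdomen plus wings) at the bottom.  A
per-pixel 95th-percentile projection over the aligned stack removes the
legs — a moving leg darkens a given pixel in at most a frame or two, so
a high order statistic restores the background beneath it.  The
percentile uses the linear-interpolation order-statistic convention
(`numpy.percentile`, `method="linear"`); with small stacks the
convention matters and is therefore pinned and oracle-tested.

The projection is closed with a grayscale disk (radius 2), erasing dark
structures thinner than the element (veins, bristles), and thresholded.
The threshold is a three-class multi-Otsu with the lower level taken:
the histogram has three modes (opaque body, translucent wing blade,
background), and plain two-class Otsu would merge the wing blades into
the body.  The silhouette is split into head/thorax/abdomen by a
marker-based watershed on the negated distance transform, the markers
being the three strongest distance maxima separated axially by at least
`body.min_marker_separation` (45 px).  Label 1 is the head, identified
as the smaller terminal segment.  Each segment's contour gets a
least-squares ellipse; lengths and widths are reported as the axial and
lateral extents of that ellipse (robust when a near-circular head fit
swaps its major and minor axes).

Shoulder width is the thorax-template scale times the template's
reference width — with an isotropic scale this reduces to the fitted
lateral thorax width, but the indirection keeps the definition explicit
and configurable.

## Sex calling

Two independent methods are fused:

1. **Abdominal luminance.** The red-channel luminance along the
   abdomen's anterior–posterior axis is resampled to 100 points,
   normalised by its mean (making it invariant to flash intensity), and
   Pearson-correlated at zero lag against packaged male and female
   template curves.  Zero lag suffices because profiles are arc-length
   normalised.  The templates ship as the mean of 50 generator-sampled
   profiles per sex and are user-replaceable with templates from real
   data (two-column CSV).
2. **Sex combs.** Frames are scanned in the region anterior to the head
   for compact dark spots attached to a foreleg, in the raw red frames
   (alignment interpolation smears leg edges through the comb intensity
   band and fabricates spots).  Candidate regions are filtered by
   luminance band, area, and eccentricity ≤ 0.95 — a leg crossing the
   antennae produces a near-degenerate ellipse and is rejected.  The
   confidence is the fraction of frames with a detection times a
   saturating function of mean spot area.

Fusion: combs exist only in males, so comb confidence ≥ `sex.tau_comb`
(0.3) forces a male call; otherwise a correlation margin ≥ `sex.tau_lum`
(0.15) decides; a missing comb is itself weak evidence for female, so a
female-leaning margin of `tau_lum/2` suffices; anything weaker is
`unknown` and left to the user.

## Interocular distance

On the brightest red frame (maximum mean luminance, first-wins ties)
the head ROI is cut from the body model, the ocelli triangle is found
by normalised cross-correlation against a synthetic three-dot template,
and each posterior dot is re-centred on its local luminance maximum with
quadratic sub-pixel interpolation — landmark precision dominates the
IOD error budget, so sub-pixel refinement is worth it, and it also
absorbs the fly-to-fly ocelli-scale difference that a fixed template
cannot.  Luminance is then sampled along the line through both
posterior ocelli, smoothed (σ = 1 px), differentiated, and the
*outermost* derivative-magnitude peak above `head.edge_threshold` on
each side is taken as the inner eye edge; the IOD is the distance
between the two.  "Outermost above threshold" rather than "global max"
keeps ocelli and cuticle texture from shadowing the true edge; the
scan is confined to the head silhouette so that background clutter and
crossing legs beyond the head cannot offer spurious outermost edges.

## Wing measurement

The wing is assembled from both channels of the brightest red frame:
blue-channel curves inside the (filled) membrane region off the body,
red-channel dark curves inside the body.  A band around the body
boundary is excluded because alignment interpolation grades the strong
body edge through every intensity band.  The union is skeletonized to
one-pixel curves, split by side, and a template consisting of the
outline plus longitudinal veins L2–L5 is fitted per side:

1. **similarity stage** — trimmed ICP from an informed initialisation
   (hinge at the posterior dorsal thorax, wing axis ~20° off the body
   axis, scale from the skeleton's radial extent);
2. **displacement-field stage** — every template sample may move only
   along its local curve normal, by a displacement clipped to ±4 px and
   smoothed along the curve by normalised convolution over the
   supported samples (σ = 2 samples); one re-assignment round follows
   (`wing.fit_iterations`, default 2).  The constraints are the point:
   free snap-and-refit updates proved unstable — tangential sliding
   folds the outline into a self-intersecting polygon and inflates the
   enclosed area, and unconstrained iteration lets the field drift on
   wings held tight against the body.  Under the field formulation,
   unsupported stretches (body-boundary cuts, junction dropouts) decay
   back to the backbone placement instead of ballooning.  Skeleton
   points ambiguous between two curves (junction blobs where a vein
   meets the outline, closely parallel proximal curves) are discarded.
   After the first pass the similarity backbone is re-estimated from
   the supported samples and, if it fits the skeleton better, the field
   is recomputed from the corrected placement — the trimmed ICP can
   settle a few pixels off when parts of the wing are hidden, and every
   unsupported stretch inherits that error otherwise.  The final curves
   are cubic smoothing B-splines through the refined samples with a
   deliberately small factor (s = 0.05·n) so the high-curvature wing
   tip is not eroded.

Each wing's skeleton is gathered by connected component, with
components assigned to a side by their centroid relative to the body
axis: with the wings held close over the abdomen their posterior rims
run within a few pixels of the midline, where a hard column split
would sever them.  The membrane mask is opened (3×3) first because
alignment interpolation leaves thin halo rings around the legs inside
the membrane luminance band.

Landmarks: the hinge is the template's proximal anchor through the
similarity transform; vein–outline landmarks are proper curve
intersections (the distal vein extended along its end tangent,
intersected with the outline spline) — the nearest-outline-point
shortcut slides along the rim wherever a vein meets it at a shallow
angle and biases wing width.  Wing length is hinge→(outline∩L3), wing
width (outline∩L2)→(outline∩L5), wing area the shoelace area of the
outline sampled at 512 points.  Both sides are fitted when present and
the side with the smaller median skeleton residual is reported,
mirroring the "intact left or otherwise right wing" convention of
manual wing mounting.  A vein whose distal half lacks skeleton support
is flagged unfitted; WL/WW are reported only if their defining veins
are present (L4 is not needed by any landmark).

CLAHE contrast enhancement is available (`wingmetrics.enhance_contrast`,
clip limit 2.0, 8×8 tiles) for low-contrast real imagery; the default
batch path does not apply it because the synthetic scenes are already
globally high-contrast and the structure thresholds are calibrated on
raw levels.  The threshold bands themselves are config-exposed.

## Validation statistics

Agreement between two methods measuring the same flies is summarised by
a bi-square (Tukey biweight) robust linear regression — IRLS with
c = 4.685, scale re-estimated each iteration as MAD/0.6745, convergence
at parameter change < 1e-8 or 50 iterations — plus residuals expressed
in percent of the reference value, Pearson correlation, and box-plot
summaries (linear-interpolation quartiles; outliers beyond 1.5 box
widths from the quartiles).  Residuals are fit-based by default
(`y − fit(x)`, in % of `x`); a raw mode (`y − x`) is available via
flag.  The IRLS is implemented here because its conventions are part of
the contract; the test suite cross-checks it against an independent
robust-regression implementation and against closed-form OLS in the
no-outlier limit.

## Selection

Relative wing size defaults to `wa / sw²` — an area over a length
squared, dimensionless, so overall body size cancels; the criterion
is fully configurable (`wl/sw`, `wl/iod`, …) since no canonical
normalisation formula exists.  Per sex, flies are ranked and the top
and bottom `n` wells reported; unknown-sex and excluded wells (damaged
wings, double occupancy — supplied as a CSV of well indices) never
enter the ranking; ties break on fly id so reruns are identical.

## The synthetic generator

`flywalk.synthio` renders flies with exact ground truth so every stage
has an oracle.  A fly is three overlapping ellipses (head, thorax,
abdomen) on a vertical axis; wings are the same canonical spline
template used by the fitter, scaled per fly and mirrored per side;
six legs (two segments each) move between frames; ocelli, eyes with
inner edges exactly `iod_true` apart, the sex-dependent abdominal
gradient (males: sharp posterior darkening; females: lighter with
tergite banding) and male forelegs with ~10 px² sex combs in ≥ 60 % of
frames complete the scene.  Trait distributions are normal with
sex-specific means (females larger: e.g. wing scale 230 ± 9 px vs
200 ± 8 px), coupled through a latent common size factor (SD 4 %) so
traits correlate as in real animals.  Default image 1800×600 px
(portrait tunnel), 6 frames, additive Gaussian noise SD 2, per-frame
pose jitter (±10 px, ±6°) and a ±2 % red flash-gain wobble.  Configured
nuisances inject defocus (σ = 4), border contact, saturated wing
reflections, 25° body tilt, and asymmetric wing posture (8°/36°) into
chosen frames; each is calibrated to trip exactly its matching QC check.

What the generator does **not** emulate: 3-D posture (pitch/roll), the
main residual error source for body traits in real imagery; realistic
texture, shading, or optics; genotype-dependent luminance patterns;
damaged or folded-wing morphologies beyond the posture nuisance;
motion blur.  Passing the recovery tests therefore demonstrates that
the algorithms are correct and self-consistent on geometry they can
see, not that the calibrated thresholds transfer to any particular
real rig — on real data the QC thresholds, luminance templates and
structure bands are the parameters to re-tune first.

## Problem sizes and tolerances

The packaged recovery study simulates 50 clean mixed-sex flies at
6 frames each, a size chosen so the full study (render + analyse)
completes in a few minutes on one core while leaving the correlation
estimates stable; the QC robustness grid uses 100 frames across 10
flies.  At these sizes the pipeline recovers wing traits with r ≥ 0.98
and robust residual SD ≤ 2 %, body traits with r ≥ 0.9, and calls sex
without error on clean renders; `scripts/acceptance.py` recomputes all
of these from scratch.  Determinism is exact: all randomness flows from
explicit seeds, and simulate→analyse twice with the same seed produces
byte-identical images and CSVs.

## Known limitations

* Segment lengths (not widths) are biased slightly short because the
  watershed cut truncates each lobe; widths, SW included, are unbiased.
* One wing per fly is measured; bilateral asymmetry is not quantified.
* The eccentricity cutoff (0.95) and comb-area normalisation are
  calibration choices on synthetic combs; real sex-comb appearance will
  need re-calibration.
* Batch processing is single-threaded by design (determinism first);
  throughput is ~3–5 s per fly at the default image size.
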