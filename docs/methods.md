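# Methods

This note documents the models, conventions and numerical choices behind
`cowtof`: what the synthetic scenes emulate, how each detection stage is
defined, which parameters matter, and what the passing test suite does and
does not establish about real barn data.

## Coordinate and unit conventions

Frames are `(rows, cols)` arrays of per-pixel distance from the camera in
metres; row 0 is the upper image boundary. The cow walks head-first from
the upper toward the lower boundary, so at the feeder its rear (tail) lies
toward the top of the image. Surface heights are centimetres above the
floor, `height = (camera_height − depth)·100`. Metric trait units use a
pinhole model: at working depth *d* one pixel spans `100·d/focal_px` cm
(`focal_px` = 222 px by default, consistent with the sensor's ~44° × ~35°
field of view at 176 × 144 px). All tolerances live in
`cowtof.config.PipelineConfig` and can be overridden from a TOML file.

## The synthetic scene model

The generator exists to give every detection stage an exactly known
target. The empty box is a floor plane at the camera height (2.55 m, the
mounting height of the emulated installation) with two side walls; the
default scenery places the left wall at the image edge and the right wall
inside the view at column 169 — mirroring the emulated box, where a high
stone wall bounds the view on the left while a lower wooden wall stands
inside the field of view on the right. Per-pixel Gaussian depth noise
defaults to σ = 1 cm, the sensor's stated accuracy; a stress mode up to
10 cm reflects the larger deviations observed in barns.

The cow back is a sum of analytic components, chosen so that every
landmark has a closed-form location:

* a **domed torso**: elliptical cross-section of relief 25 cm (HF-like) or
  10 cm (FV-like) on a constant clearance, crest at the body axis;
* a **backbone ridge**: narrow Gaussian (σ = 4 px) whose amplitude ramps
  from 15% at the rump to 100% at mid-body, so the sacrum region stays low
  while the per-row height maximum always lies on the axis;
* **pin bones, hips**: positive Gaussian bumps; **dishes of the rump**:
  negative Gaussians. Pin and dish bumps are rendered in the plane of the
  dish cut;
* a narrow **tail ridge** (2.5 px half-width) protruding toward the upper
  boundary, 28 cm below the crest.

The rear contour (mask boundary toward the upper image boundary) is
modelled per pelvis class. The HF-like contour is a parabolic rump with
explicit pin-bone protrusions and, for deep dishes, contour recessions;
its signature therefore shows a tail peak flanked by explicit minima and
pin maxima of comparable height (tail and pins near-equidistant from the
centre of mass, within 10%). The FV-like contour is a circular arc around
the expected centre of mass whose radius tapers by 0.1 px per pixel of
lateral offset: the signature declines gently from a dominant tail peak
("segues into a flat course"), the tail is clearly (>10%) the farthest
boundary point, and no explicit dish minima exist. Because the flat-dish
landmarks are *defined* by the contour rules (dish at the curvature
maximum at the tail-bump base, pins halfway to the signature's drop
point), the generator applies those rules to its own noise-free contour,
per side, and renders the surface bumps there; shapes whose contour admits
no such features are rendered with plausible fallback positions and fail
the cascade by design.

Ground-truth boundary landmarks are snapped to the pixel grid the way the
detector sees them: the landmark column first (ties breaking away from the
axis, which keeps mirrored landmarks mirrored), then that column's first
masked row. Hip ground truth is the *actual* local maximum of the analytic
surface (the dome slope shifts it slightly axis-ward of the bump centre),
refined on a 0.01-px grid.

An overhanging tail (`tail_overhang` > 0) is rendered as a sideways-bent
diagonal pixel chain connected to the rump: the gap it leaves between the
outer and inner hind boundary curves tracks the parameter, so frames with
`tail_overhang` beyond the HindBoundaryCurve tolerance fail that test.

Walk-through dynamics: `body_advance` is the row reached by the muzzle
end; the mask touches the lower boundary iff `body_advance ≥
frame_height − 1`, and the tail becomes fully visible at the dwell value
`rear_row + body_len`. Entry/exit frames therefore fail the position test
exactly as labelled by the generator.

What the generator does **not** emulate: fur/colour-dependent TOF
reflectivity, multipath near steep slopes, motion blur, udders and legs,
multiple animals, and lens distortion. Passing tests show the algorithms
are correct on geometrically faithful surfaces under Gaussian sensor
noise; they do not certify the error rates achievable in a barn.

## Detection stages: definitions and tolerances

**Empty-scene test.** Columns whose median depth deviates from the camera
height are treated as static wall structure; among the remaining pixels,
at most 1% may deviate by more than 5 cm. **Wall detection** takes the
column-wise median of the horizontal depth gradient of the mean map and
returns the strongest positive (left) and negative (right) jump; it
handles walls of unequal height.

**Segmentation.** Difference test with `k = 3` and a 0.5 cm SD floor.
The histogram confirmation requires the candidate pixels' depth mode to be
separated from the background mode by ≥ 10 cm with a clear valley. Two
cleanup steps make the mask noise-robust without moving smooth contours:
candidate pixels whose depth lies more than 35 cm from the candidate
median are dropped (floor pixels with extreme noise fused to the rim), and
pixels with fewer than 3 of 8 neighbours are pruned (diagonal speckle; a
coherent surface pixel always keeps ≥ 3). The mask is then the largest
8-connected component, and the position test requires contact with the
bottom row plus a ≥ 10-row gap to the top.

**Signature.** Distances from the foreground centre of mass to the outer
hind-boundary points, ordered by column; local structure is read from a
5-point moving average. The raw second difference of the signature
oscillates with the integer-row staircase of the boundary, so the
curvature used for flat-dish localisation is averaged over the staircase
period and its peak refined parabolically; a peak at the search-window
edge signals a degenerate signature and rejects the side. The tail must
lie within 15° of the body axis; deep dishes need ≥ 1 px prominence; the
flat-course gradient bound is 0.35 px/px; the FV drop tolerance is 0.85 of
the tail value, and a drop closer than 4 samples to the dish is treated as
degenerate. Frames with both dishes deep use the adjacent-maxima
tuberosity rule regardless of breed; both flat is accepted only for the
FV path; mixed classes reject the frame.

**Backbone and hips.** The backbone is the least-squares line through the
per-row minimal-depth columns, excluding the rearmost 20% of mask rows
(tail-dominated). Hips are the tallest smoothed-height local maxima per
body side in the forward half, outside a 10-px backbone band, preferring
maximal lateral distance among near-equal candidates.

**Anatomical validation.** Left/right distances (knuckles to tail, hips to
backbone) must agree within 15% — with a 3-px floor, since a relative
tolerance is meaningless at pixel scale near the tail — and landmark
depths within 2 cm, read as 5×5 foreground medians for noise robustness.

**Code triples.** ImageBorder (2-px margins) and HindBoundaryCurve
(tolerance 3 rows) are always evaluated and recorded as
`(hind, left, right)`; landmarks are attempted only for `1-1-1` and
reported only for fully valid frames. Because segmentation confines the
foreground strictly between the walls and the right wall stands inside the
image, the right border test cannot fail under the default scenery — the
four `·-·-0` code groups are structurally empty over any processed batch.

## Trait extraction

Profiles are bilinear samples (100 points) of the depth image with the
background nearest-neighbour-filled so boundary samples are not dragged
toward zero. The dish cut runs perpendicular to the backbone through a
point 6 px forward of the midpoint of the two contour dish landmarks: the
contour landmark sits on the mask boundary, where a perpendicular cut
would not span the pin bones; a few pixels forward the rump surface
carries the dips and both flanking maxima. Closing-line flanks are the
per-side maxima of the lightly smoothed profile between the cut end and
the backbone crossing; depth and volume are then measured on the raw
profile against the chord joining the flanks, so noise-free oracles are
exact. Distortion/area traits compare a degree-4 polynomial fit of the
diagonal profiles with the straight line joining the raw endpoints; the
area integrates the unsigned difference so crossings do not cancel. The
degree is 4 rather than 3 because a cubic underestimates a symmetric
bump's amplitude by ~2% (it adds no even term beyond the parabola),
which already exceeds the closed-form tolerance the integrals are held to.
Profile smoothing leaves the first and last half-window untouched so
tangent levels and chord anchors are unbiased. All smoothing choices
preserve integrals of smooth profiles to well under 1%, verified against
triangle (d·w/2), parabola (⅔·d·w) and sinusoid ((2/π)·a·L) closed forms.

## Statistical layer

Daily cleaning removes values outside median ± 3·scaled-MAD (consistency
constant 1.4826); with zero MAD only the median value survives. Weekly
aggregation keys on ISO calendar weeks and joins the weekly BFT (and BCS)
reference. The season mapping is fixed: weeks 49–52 and 1–9 → season 1,
10–22 → 2, 23–35 → 3, 36–48 → 4.

The coefficient-of-determination model is a generalized linear model with
a continuous one-knot piecewise-linear link `f(y) = y + (s−1)·(y−κ)₊`
fitted to predictors constant + lactation week + trait starting level. For
each candidate knot κ (deciles of y by default) the second slope *s* is
estimated jointly with the coefficients as a single linear least-squares
problem — the hinge enters as a response-side column — and the knot with
minimal residual sum of squares wins; R² is computed on the transformed
scale and lies in [0, 1] by construction. This estimation scheme is this
package's own design: the link's exact estimation in the original software
is not recoverable, and the joint-linear formulation keeps the search
exact and fast. Per-cow fits drop the starting level (constant within a
cow) and require ≥ 16 weeks of records.

Effect sizes are plain one-way ANOVA η² = SS_between/SS_total with the F
test at α = 0.05 deciding whether an effect is reported; group-mean plots
show t-based 95% confidence intervals.

The longitudinal simulator draws `baseline + cow + season + residual`
with per-trait components. Cow effects are rescaled to their exact design
SD, so a designed η² (e.g. 0.7: `σ_cow = √(0.7/0.3)·σ_e` with no season
effects) is realised in every dataset rather than only in expectation —
the closed-form value `σ_c²/(σ_c² + Var(season sequence) + σ_e²)` is then
recoverable to within a few hundredths at 50 cows × 40 weeks. Default
baselines are round plausible magnitudes, not measured values.

## Problem sizes and determinism

The standard verification runs use 176 × 144 px frames, 20–30 calibration
frames, 100 jittered shapes per pelvis class for the landmark batteries,
and 50 cows × 40 weeks for variance-component recovery; these sizes make
the whole suite run in well under a minute while leaving the statistical
assertions comfortable margins. All randomness flows through
`numpy.random.Generator` seeds; rendering and stream processing are
byte-reproducible for identical seeds and configs.

## Known limitations

* The generator's two pelvis classes are stylised extremes; real herds
  show intermediate signatures that may mix the deep- and flat-dish rules
  within one animal over time.
* The flat-dish ("FV") tuberosity rule is a coarse geometric construction;
  its placement is only as anatomically meaningful as the drop-tolerance
  calibration.
* Trait magnitudes depend on the pinhole focal length and the dish-cut
  forward offset; absolute values are comparable only within a fixed
  configuration.
* Noise inflates the max-gap dish depths (extreme-value bias of the
  maximum over a noisy profile); day-level averaging mitigates but does
  not remove this.
* Frames with two animals or heavy occlusion are expected to fail the
  cascade rather than be handled.
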