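# cowtof

Automated body-condition monitoring of dairy cows from top-view
time-of-flight (TOF) depth images.

Body condition — the fat cover over a cow's pelvis — is traditionally
scored by eye and palpation (BCS, a 1–5 scale in quarter points) or by
ultrasound backfat-thickness measurement (BFT, mm). Both are laborious and
stress the animals. A downward-looking TOF camera mounted over a feeding
box sees each visiting cow's lower back as a per-pixel distance map, and
the sunkenness of the rump surface carries the same information. `cowtof`
implements the full processing chain of such a system, plus a parametric
synthetic depth-scene generator with exact ground truth, so every stage is
testable without camera hardware or farm recordings.

## What the pipeline does

1. **Calibration** (`cowtof.calib`) — from frames of the empty box, a
   background model: per-pixel mean and SD of the depth (`mean_map`,
   `std_map`) and the wall columns located from horizontal depth gradients.
2. **Sorting and segmentation** (`cowtof.segment`) — a frame is kept only
   if it shows a cow's lower back: a moving object found by the difference
   test `|IMG − meanIMG| > k·max(stdIMG, σ_floor)`, confirmed by depth-value
   histograms, restricted to its largest connected component, and placed so
   that the body intersects the lower image boundary while keeping distance
   to the upper one. The background is set to zero.
3. **Region of interest** (`cowtof.roi`) — a multistage test battery:
   ImageBorder (left/right), HindBoundaryCurve (outer vs. inner rear
   contour), then — only for code triple `1-1-1` — landmark detection on
   the **signature**, the sequence of distances from the cow area's centre
   of mass to its rear boundary points. The tail is the signature maximum
   aligned with the centre of mass; the dishes of the rump are explicit
   local minima beside the tail bump ("deep") or sit at the maximal
   curvature where the signature segues into a flat course ("flat");
   ischeal tuberosities follow breed-specific rules (Holstein Friesian:
   adjacent local maxima beyond deep dishes; Fleckvieh: halfway between a
   flat dish and the signature's drop point). A linear fit to the per-row
   highest back points gives the backbone, lateral height bumps in the
   forward body half give the hips, and a left/right anatomical symmetry
   check validates the frame.
4. **Trait extraction** (`cowtof.traits`) — 13 *camera traits* from height
   profiles along straight cuts (cm/cm² via a pinhole model): `hip2hip`
   (area under the hip-to-hip profile's horizontal tangent), dish depths
   and volumes under closing lines on a cut perpendicular to the backbone,
   and the maximal distortions and enclosed areas between polynomial
   approximations of the hip→tuberosity ("pin") and hip→dish ("mid")
   diagonal profiles and their straight connecting lines.
5. **Statistics** (`cowtof.stats`) — outlier cleaning (median ± 3·MAD),
   daily and weekly aggregation against the BFT/BCS reference, Pearson
   correlations with significance, coefficients of determination from a
   generalized linear model with a one-knot piecewise-linear link (overall
   and per cow), calendar-week season grouping (weeks 49–52 & 1–9 → season
   1; 10–22 → 2; 23–35 → 3; 36–48 → 4), and one-way-ANOVA effect sizes
   (η² = SS_between/SS_total) for cow and season.
6. **Orchestration** (`cowtof.pipeline`, `cowtof` CLI) — stream processing
   into per-day lists with code-triple accounting.

The generator (`cowtof.tofsim`) renders the empty box and parametric cow
backs in the two pelvis-shape classes with exact landmark ground truth, and
simulates longitudinal trait datasets with known variance components.

## Worked example

```sh
cowtof simulate --breed hf --frames 8 --noise 0 --seed 1 --out demo/stream
cowtof calibrate --in demo/stream --out demo/scenery
cowtof process --in demo/stream --scenery demo/scenery --breed hf --out demo/day.csv
```

The simulated stream holds 33 frames: 25 of the empty box, then one visit
(3 entering, 2 dwell, 3 leaving). Processing prints the day summary:

```
{
 "n_frames": 33,
 "n_kept": 2,
 "kept_fraction": 0.06060606060606061,
 "n_valid": 2,
 "code_counts": {"1-1-1": 2, "1-0-1": 0, "0-1-1": 0, "0-0-1": 0,
                 "1-1-0": 0, "1-0-0": 0, "0-1-0": 0, "0-0-0": 0},
 "stage_counts": {"rejected_no_object": 25, "rejected_position_fail": 6}
}
```

Only the two dwell frames show the lower back and are kept (the empty and
walk-through frames are rejected), both pass every ROI test (code `1-1-1`),
and each contributes a 13-trait row to `demo/day.csv`:

```
cow_id  frame code_triple   HH   DL   DR  DPL   AML
cow001     28       1-1-1 82.8 2.95 2.97 3.95 57.48
cow001     29       1-1-1 82.8 2.95 2.97 3.95 57.48
```

`HH` is the hip-to-hip dip area (82.8 cm²); `DL`/`DR` are the measured dish
depths — the scene was rendered with 3 cm deep dishes, recovered here as
2.95/2.97 cm; `DPL` and `AML` are a diagonal-cut distortion (cm) and area
(cm²). A `cowtof stats` command aggregates day lists into weekly records
and writes descriptive and effect-size tables.

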