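# Methods

This note records the scoring procedure, the synthetic-data model behind
the test suite and the acceptance script, and the numerical and design
choices that were genuinely open.

## Evaluation procedure

Per subject, the pipeline compares a reference segmentation (RS) with an
automated one (AS) on a shared voxel grid. All computation is in voxel
index space; grids must match in shape, and spacing within a relative
tolerance of 1e-4. No resampling or registration is ever performed — pairs
on incompatible grids are refused, because silently resampling a mask
changes the quantity being evaluated.

1. **Cluster filter.** Both maps are decomposed into maximal 26-connected
   components and clusters of fewer than 10 voxels are removed. The filter
   is applied to reference and automated maps alike, once, at whole-brain
   level (a flag can exempt the reference for sensitivity analyses).
   Filtering precedes any regional restriction so that lesions straddling a
   region border are not filtered a second time at regional scale.
2. **Voxel metrics.** DSC, sensitivity, precision from the voxel counts of
   RS, AS and their intersection; volumes in mL via the voxel volume.
3. **Lesion matching.** Reference lesion *r* is detected if an automated
   lesion *a* exists with overlap ≥ 10 % of |r| and overlap ≤ 70 % of |a|.
   Matching is many-to-many (no assignment problem is solved): one
   automated lesion may validate several reference lesions and vice versa,
   and TP is counted on the reference side. Lesion precision is therefore
   reported unclamped and can exceed 1 in pathological configurations; a
   warning is logged when it does.
4. **Cohort aggregation.** Mean and sample SD (n−1) per method/region/
   metric; ICC(2,1) of total volumes; extreme burden subgroups; Koo–Li
   qualitative bands.

### The 70 % clause

The double overlap rule admits two readings. The *literal* one
(overlap/|a| ≤ 0.70) is the default because it is the rule as stated, but
it has the surprising consequence that an automated lesion entirely inside
a reference lesion (overlap/|a| = 1) never validates it — identical masks
do not self-match. The *outside* reading ((|a|−overlap)/|a| ≤ 0.70), in the
style of the multiple-sclerosis lesion-detection literature this rule
descends from, accepts contained lesions and makes identical masks score
F1 = 1. Both are implemented and the active rule is named in every report;
the package does not guess which was intended.

### Degenerate masks

Ratios with empty denominators are not imputed. Both masks empty: DSC = 1,
sensitivity and precision undefined. Reference empty, automated not:
DSC = 0, sensitivity undefined, precision = 0 (and symmetrically). Undefined
values propagate as NaN, are excluded from cohort means, and their count is
reported per cell. This avoids 0/0 while still penalizing asymmetric
failures in DSC.

### ICC(2,1)

Two-way random effects, absolute agreement, single measurement: with
between-subject, between-rater and residual mean squares MSR, MSC, MSE of
the n×2 volume table (k = 2 raters: reference and tool),

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

A table with zero total variance is defined as ICC = 1 (identical constant
ratings are perfect agreement). Negative residual sums of squares from
float cancellation are clamped at 0. ICC is computed on volumes in mL;
scale invariance makes the unit immaterial on a shared grid (asserted by
test). Category boundaries: the verbal bands overlap at their endpoints,
so 0.75 and 0.90 are both assigned to "good".

### Threshold tuning

The probability-map threshold is searched on an inclusive arithmetic grid
(default 0 to 0.95, step 0.05; grid values rounded to 1e-9 so the printed
endpoints are exact). For each value the maps are binarized with a strict
comparison (value > t — the tie direction is a convention, stated here
because it is observable at t = 0 and on quantized maps), cluster-filtered
and scored; the objective is mean DSC across training subjects, the
package's headline similarity measure. Ties break toward the smaller
threshold for reproducibility. External tools' own hyperparameters (a WM
mask threshold, the LGA kappa) are tuned through the same machinery over
precomputed candidate volumes indexed by parameter value; running those
tools is out of scope.

## Synthetic cohort model

The generator stands in for cohort imaging data and defines the conditions
under which the pipeline is tested; its defaults are fixed study
conditions, not tuning knobs.

- **Grid**: 64×64×64 voxels at 1.75 mm isotropic — a deliberately
  scaled-down FLAIR grid that keeps a 30-subject cohort evaluable in
  seconds. One consequence is acknowledged: the 10-voxel filter cuts at
  ~54 mm³ here instead of ~10 mm³ on a 1 mm grid, so surviving lesion
  counts per subject are lower than in real cohorts.
- **Lesions**: Poisson(40) count per subject; axis-aligned random
  ellipsoids with log-normal base radii (σ = 0.55) rescaled per subject so
  the summed volume hits that subject's burden target; placed disjointly
  (1-voxel Chebyshev gap, so placed blobs are distinct 26-components)
  inside an ellipsoidal brain support, away from the support edge where
  possible.
- **Burden profile**: per-subject target loads follow a geometric
  (exponential-in-quantile) profile calibrated by bisection so the extreme
  terciles of a 30-subject cohort average 1.65 and 20.22 mL — the subgroup
  means the reporting conventions are built around — with ±10 % log-normal
  jitter and random assignment to subject indices. Realized loads span
  roughly 0.6–50 mL.
- **Degradation** (automated-mask emulator), applied in order: rigid
  integer displacement (default 1 voxel); optional boundary
  dilation/erosion (default 0 — at 1.75 mm a single-voxel dilation is a
  gross, unrealistic error; the default error budget lives in the other
  three terms); size-biased lesion dropping (small lesions, < 30 voxels,
  dropped with p = 0.3; larger ones with p scaled down by 30/size);
  Poisson(5) false-positive blobs. Under these defaults a 30-subject
  cohort scores mean DSC ≈ 0.56–0.57, sensitivity ≈ 0.64, precision ≈ 0.54,
  lesion F1 ≈ 0.49 and volume ICC ≈ 0.98 — the moderate-performance,
  high-volume-agreement regime typical of published WMH tools — and
  performance rises with lesion burden.
- **Probability maps**: the degraded mask's signed Euclidean distance
  transform (positive inside, half-voxel boundary offset), lightly
  Gaussian-smoothed (σ = 0.35·w) to interpolate between the integer
  distance shells, perturbed by uniform boundary noise of half-width
  0.5·w voxels, and mapped through logistic(sd/w) followed by the monotone
  power map p → p^(ln t*/ln 0.5). The 0.5 level of the noise-free ramp is
  the mask boundary itself, so binarizing at the planted threshold t*
  (default 0.45) recovers the degraded mask and every other threshold
  erodes or dilates it by a distance offset, scoring strictly worse. Two
  constructions that look natural fail this contract and were rejected:
  Gaussian-smoothing the *indicator* erodes small lesions by curvature
  flow (the optimal threshold drifts several grid steps low), and a net
  boundary dilation in the degradation is absorbed by the threshold (the
  optimum drifts high) — so the probability-map path zeroes the net
  boundary offset and keeps only displacement, misses and false positives,
  the error modes no threshold can undo. Values are quantized to 1e-4
  before any comparison so thresholding is platform-stable.
- **Randomness**: every quantity is drawn from a named per-subject
  sub-stream (burden, placement, degradation, false positives) seeded by
  (cohort seed, subject index, stream id), so toggling one degradation
  never shifts the draws of another, and identical seeds give identical
  cohorts at the voxel level.

What the generator does *not* model: MRI intensities and contrast, bias
fields, periventricular lesion geometry, rater variability, scanner/site
effects. Passing tests therefore demonstrate the correctness and the
statistical behaviour of the *scoring machinery*, not the accuracy of any
real segmentation tool on clinical images.

## Problem sizes in tests and the acceptance script

The test suite runs the component-labelling oracle on 1000 random masks up
to 24³, the metric identities on 1000 random pairs, the ICC oracle on 200
random tables, lesion matching against brute force on 500 instances, and
threshold recovery on 100 cohorts of 10 subjects at 40³ — sizes chosen so
the full suite completes in a few minutes while keeping every check at
cohort scale. The acceptance script uses the full default configuration
(30 subjects, 64³).

## Known limitations

- Orientation metadata is carried but never interpreted; volumes in
  different anatomical orientations but equal shape/spacing compare in
  index space with only a logged warning.
- Lesion-level metrics are whole-brain only (regional rows carry voxel
  metrics), matching the reporting convention the package targets.
- The burden split requires 2k ≤ n and excludes the middle of the cohort
  by construction; with heavy ties at the subgroup boundary the split is
  deterministic (ties break by subject id) but somewhat arbitrary.
- `tune_threshold` loads all candidate thresholds over the same in-memory
  cohort; very large cohorts should be tuned in batches.
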