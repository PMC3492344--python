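# Methods

## Model and assumptions

`flyfluor` assigns genotype labels from fluorescence images under three
assumptions: (1) tracking supplies a correct, head-ward-oriented pose for
every fly in every fluorescence frame, in the same pixel coordinates as the
images; (2) the GFP marker concentrates in the anterior body half (thorax),
while non-specific autofluorescence is strongest in the abdomen; (3)
illumination may vary across the arena and between rigs, but multiplicative
intensity changes affect front and rear of a fly, and all moments of its
intensity histogram, proportionally. Assumption (3) is why both shipped
metrics are dimensionless — a ratio of like quantities and a standardized
moment — and why no flat-field or background correction is applied.

## Regions of interest

The Total ROI is an oriented rectangle centered on the tracked centroid,
aligned with the body axis, with half-extents `length_scale·a` and
`width_scale·b` (defaults 1.2, chosen so the box encloses the fitted body
ellipse with a small margin; both are configurable and persisted with the
calibration). The front/rear split plane is perpendicular to the body axis
at a configurable fraction of the box length (default 0.5, recorded in the
calibration artifact). Tracked orientations are taken as head-ward;
importers can flip all angles if the tracker's convention is reversed.

Pixel membership is by pixel center, with a half-open rule along both local
axes (low edge in, high edge out) and a 1e-9 tolerance. The half-open rule
is deliberate: it makes the rasterized Front and Rear ROIs tile the Total
ROI exactly — a pixel centered on the split plane belongs to the front half
and only the front half — so no intensity is dropped or double-counted. A
symmetric strict-inside rule cannot achieve this. Whether the original
analyses used oriented or axis-aligned boxes is not determinable; oriented
boxes are implemented because they follow the animal and keep the
front/rear semantics exact at every heading.

## Metrics

* `max5_ratio`: per image, the mean of the `k = max(1, ceil(0.05·n))`
  brightest Front pixels and the same for the Rear ROI; the per-image
  numerators and denominators are averaged separately over images before
  dividing (ratio-of-averages). The `ceil`-with-floor-1 rule keeps the
  statistic defined for arbitrarily small ROIs and is deterministic.
* `skewness`: the biased (divisor-`n`) sample skewness of the Total-ROI
  pixel vector, per image, then averaged over images (average-of-values).
  The biased estimator is the default definition of the standard numerical
  environments this field uses.
* `single_max_ratio` is shipped for comparison; it equals `max5_ratio`
  whenever every ROI has ≤ 20 pixels and is strictly less robust to hot
  pixels, which is why it is not a default.

The two default metrics live on different scales, so the combination
min-max normalizes each to [0, 1] using the calibration cohort's observed
range (clipping outside values) before forming `w·n₁ + (1−w)·n₂`. The
normalization ranges are persisted in the calibration JSON; classification
of later data reuses them unchanged.

## Calibration

Calibration data are homogeneous groups, so every fly's label is known by
construction. For each weight on a 0–1 grid in steps of 0.01, the combined
scores are swept with 1000 evenly spaced thresholds spanning their observed
range; `score ≥ θ → GFP` (equality goes to the GFP side; equality is
measure-zero for continuous scores and the rule must be deterministic).
Accuracy is `100·(1 − (FP + FN)/total)`. The operating point is the widest
plateau: among weights attaining the global maximum accuracy, the one with
the longest contiguous run of maximum-accuracy thresholds wins (ties to the
smaller weight), and θ\* is that run's midpoint. Plateau width is the
natural robustness measure here — scores must drift half a plateau before
any call changes. Whether the 1000 thresholds should be shared across
weights is an open choice; they are swept per weight over that weight's own
combined-score range, since a shared grid would waste resolution for
weights whose scores occupy a narrow band.

Degenerate cases: identical calibration scores yield a flagged
(`NonSeparableWarning`) degenerate sweep in which every fly is called GFP;
a metric with zero observed range aborts calibration naming the metric.

## Classification

Threshold mode applies (w\*, θ\*) directly; the margin `|score − θ*|` is
reported per fly for downstream quality control. Prior-count mode sorts
descending and calls the top `N` flies GFP, with ties broken by ascending
fly id so results are permutation-invariant; the margin is the distance to
the midpoint between the scores at ranks `N` and `N+1`. Prior-count mode
always returns exactly `N` GFP calls.

## Image selection

Fluorescence is acquired in two short bouts bracketing the behavioral
recording. When `n` images are used, the default mode alternates between
the front of the pre-experiment block and the front of the post-experiment
block, starting with — and, for odd `n`, giving the extra image to — the
pre block; this interleaving exploits fly movement between bouts to average
out spatial illumination inhomogeneity. The pre-first/odd-to-pre order is a
package convention fixed for determinism and recorded in output metadata.
An end-only mode uses only post-experiment frames, for protocols where
pre-experiment excitation is undesirable.

## Synthetic scenes

The generator emulates what the metrics exploit, not fly photorealism:
each fly is a filled oriented ellipse at a cuticular baseline, with a
posterior Gaussian blob (abdominal autofluorescence, all flies), an
anterior Gaussian blob (thoracic GFP, labeled flies only), and two small
anterior eye spots (non-GFP flies; the worst case of markers that drive
expression in eyes and ocelli). Scenes add a linear illumination gradient,
optional arena autofluorescence patches, and per-pixel Gaussian noise,
clipped to the 8- or 16-bit range. Overlapping intensity composes by
maximum.

Two named conditions are used throughout the tests and the reproduction
script:

* high-contrast (the `SceneConfig` defaults): 18 flies, thorax amplitude
  120, abdomen 60, eyes 40, body baseline 25, noise SD 6, 20% illumination
  gradient, 20 frames — amplitudes chosen so the GFP/non-GFP metric
  histograms separate cleanly, as they do on a well-tuned rig;
* low-SNR (`noisy_config`): identical except noise SD 60 (equal to the
  abdominal amplitude) and 40 frames, the regime where accuracy depends
  visibly on the number of images averaged.

The random walk is collision-avoiding by default (`separation_factor =
2.5` body lengths between centers): flies are solid bodies, and without
this constraint a non-GFP fly can sit on a GFP neighbor's thorax for a
whole scene, putting an irreducible floor under the error rate of *any*
intensity metric. Setting `separation_factor = 0` restores free overlap
for tests that want to exercise ROI contamination. Everything — poses,
labels, pixels — is reproducible from the config seed.

What the generator does not emulate: wings and legs, body-shape variation
beyond ellipse-axis jitter, photobleaching, tracking errors (poses are
exact), occlusion by arena walls, and rig-to-rig illumination drift between
calibration and test scenes. The last point matters for interpretation:
with zero drift, a fixed calibrated threshold performs unusually well, so
the measured advantage of prior-count mode over threshold mode on these
scenes (≈ +0.3 points averaged over image counts in the low-SNR condition)
understates its value on real, drifting rigs. Passing tests therefore
demonstrate correctness of the machinery and the qualitative structure
(separable regime → 100%; accuracy rising with image count), not the
field performance of any particular rig.

## Problem sizes

The reproduction script (`scripts/acceptance.py`) uses 15 + 15 homogeneous
scenes and 15 mixed scenes of 18 flies for the high-contrast condition, and
5 + 5 calibration scenes plus 30 replicate mixed scenes at image counts
{1, 2, 4, 10, 20} for the low-SNR condition. The test suite uses the same
sizes, with 60 replicates for the low-SNR curves so that the seed-averaged
mode comparison is resolved to better than one percentage point.

## Known limitations

* Identity is per trajectory: if tracking swaps two flies mid-experiment,
  the call applies to the trajectory, not the animal.
* Heavily overlapping flies contaminate each other's ROIs; the package
  neither detects nor corrects this (the tracker is expected to keep
  identities, and the generator's default walk keeps bodies apart).
* Normalization ranges are frozen at calibration; a test cohort whose
  metric values fall far outside them saturates at the clip boundaries.
* All geometry is in pixels; physical calibration (mm/px) is left to the
  user.
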