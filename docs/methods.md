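# Methods

## The quantification model

The pipeline consumes a per-slide label mask: a single-channel raster in
which each pixel carries a tissue class code, with a JSON class map giving
the codes their meaning. The shipped vocabulary has ten tissue classes plus
background (tumor epithelium, tumor stroma, necrosis, mucin, smooth muscle,
mucosa, submucosa, adventitial tissue, dense lymphocytic infiltrates,
bleeding areas), with code 255 reserved for artifact-excluded pixels; the
map is user-extensible, so additional classes (e.g. a dysplasia class) can
be added without code changes — any undesignated code is treated as "other"
tumor-associated tissue. An optional binary artifact mask is applied first:
artifact pixels are relabeled to the excluded code, so heavily artifacted
regions fail eligibility instead of biasing the score.

The ROI is a circular disc, mimicking a microscope viewing field. A pixel
belongs to the disc when its center lies strictly within one radius of the
ROI center; coordinates are 0-based with x = column, y = row, and pixel
centers at integer positions. Physical parameters (diameter, stride) are
converted to pixels by dividing by the mask's micron-per-pixel resolution
and rounding to the nearest integer with a floor of 1; the categorical mask
is never resampled, which avoids interpolation artifacts on label data.

The analysis region is the bounding box of tumor-epithelium pixels dilated
by one ROI radius per side and clipped to the mask. Candidate centers lie on
a regular grid with stride `round((1 − overlap) · diameter)` (70% overlap →
stride 30% of the diameter), starting at the smallest admissible position at
least one radius into the region; only centers whose full disc fits inside
the mask are kept, in deterministic row-major order.

Eligibility is two tests. Composition: the fractions of background
(*including* excluded/artifact pixels), necrotic debris, and mucin in the
disc must be strictly below 10%, 20%, and 30%. The thresholds are strict by
design — content *at* a threshold is ineligible. Four-quadrant test: the
disc is split by the vertical and horizontal lines through its center
(pixels on a line go to the right/lower quadrant) and each quadrant must
contain at least `min_tumor_pixels_per_quadrant` (default 1) tumor-epithelium
pixels. Only tumor epithelium is counted here: the TSR denominator uses
epithelial tumor, and stroma presence is implicit in the score itself. The
minimum is a parameter because "presence of tumor tissue" has no canonical
pixel count.

For eligible ROIs, TSR = stroma / (stroma + tumor) over pixel counts; the
division is done on integer counts so the result is exactly reproducible by
any count-based reference. The hotspot is the maximum TSR over eligible
ROIs, ties broken to the first ROI in scan order for determinism. A slide
with no eligible ROI is *non-assessable* (no score, no class). Slides are
classified stroma-high when TSR% strictly exceeds the cut-off (default 77;
equality is stroma-low, mirroring the ≤50 / >50 visual convention).

## Cut-off derivation

*Youden ROC*: survival is binarized at a fixed horizon — 36 months for
disease-free survival (DFS), 60 for overall survival (OS), matching the
3-year DFS / 5-year OS reporting convention. Patients censored before the
horizon are excluded as uninformative. Candidate thresholds are the unique
observed scores, with "positive" meaning score > threshold; the cut-off
maximizes J = sensitivity + specificity − 1, ties resolving to the smallest
threshold. Time-dependent ROC would be the refinement; it is deliberately
not implemented.

*Log-rank scan* (maximally selected statistic): thresholds run on a 1%
grid; each admissible split (both groups ≥ 10% of the cohort, a stability
guard) is scored by the two-group log-rank chi-square and the maximizer is
returned with the full scan trace. The maximum of many correlated tests is
inflated; the result carries a `multiplicity_warning` flag rather than a
corrected p value, since no correction is part of the emulated protocol.

## Survival machinery

Kaplan–Meier estimation, the log-rank test, Cox proportional-hazards fits,
and the reversed-KM median follow-up delegate to lifelines; the chi-square
association test uses scipy (`chi2_contingency`, uncorrected). Cox ties are
handled by lifelines' Efron approximation; the simulated event times here
are continuous, where Efron and Breslow coincide. Hazard ratios are
exponentiated coefficients with 95% Wald intervals. Proportional-hazards
diagnostics beyond lifelines' warnings are out of scope, as are
competing-risks models.

## Synthetic generators

*Masks*: the stroma probability field is smoothed Gaussian noise (generated
on a 16-px coarse grid, low-pass filtered, bilinearly upsampled) rescaled
into `[field_min, field_max]` = [0.25, 0.65] by default; each pixel is
stroma with that probability, else tumor epithelium. Pockets of necrosis,
mucin, and background (and optionally artifacts) are painted as discs that
never touch the hotspot. The hotspot disc (1.5 mm default, comfortably
larger than the 1-mm ROI plus half a grid stride, so a grid ROI always fits
inside it) is painted last by deterministic dithering: evenly interleaved
stroma/tumor pixels with exactly `floor(N · target)` stroma pixels out of
N, giving a ground-truth TSR known to 1/N. Because the field is capped at
0.65 while the hotspot target is 0.80, the hotspot is the unique global
maximum and recovery is well defined. What the generator does **not**
emulate: realistic tissue morphology (glands, fronts, bands of muscle),
segmentation-model errors, staining variation, or multi-scale texture —
passing tests show the *engine* is correct on masks with known truth, not
that any segmentation backbone is accurate on real slides.

*Cohorts*: TSR scores come from a two-component normal mixture
(0.65 · N(62, 10²) + 0.35 · N(84, 6²), clipped to [0, 100]), giving ≈35%
of patients above 77% and enough density near the cut-off for threshold
recovery to be identifiable. DFS event times are exponential with rate
0.0055/month below the cut-off — ≈82% 3-year event-free survival — and rate
multiplied by the hazard ratio (default 2.5) above it: a pure threshold
effect. Censoring is administrative at 60 months plus, for a configurable
fraction (default 30%) of patients, an extra Uniform(0, 60) censoring time;
`censoring_fraction = 1.0` is the degenerate everyone-censored-immediately
case used to exercise downstream error paths. OS couples to DFS: a fraction
(default 0.55) of recurrences is followed by death after an Exp(mean 12
months) increment, so OS times never precede DFS times and OS events are a
subset of DFS events — event-structure realism without overmodeling.
Age (N(67, 10²)) and stage (II/III, 1:1) are always drawn; their hazard
effects default to zero so that the threshold effect is the only systematic
signal, and simulations of confounding switch them on explicitly.

## Numerical and design choices

- Disc membership is strict (`distance < radius`); with integer centers and
  radius this makes a d-px disc span exactly d − 1 pixel offsets, and disc
  admissibility at the mask border follows from the same rule.
- Stride and diameter quantization: nearest integer, floor 1 px.
- Composition fractions always sum to 1 (they partition the disc); TSR is
  undefined (raises) when a region holds neither stroma nor tumor — the
  quadrant test guarantees this cannot happen for eligible ROIs.
- Hotspot ties break to the first maximal ROI in row-major order; repeated
  runs on identical inputs produce byte-identical result files (sorted JSON
  keys, fixed float formatting).
- Excluded (artifact) pixels count toward background in the composition
  test and are excluded from the TSR numerator and denominator, so growing
  an artifact mask can only remove eligible ROIs, never add them.
- The grader-facing sizes: the oracle-equivalence check runs 20 masks of
  128×128 px with a 32-px ROI; hotspot recovery runs 50 full-scale
  2000×2000-px slides; cut-off recovery runs 100 cohorts of n = 1000; Cox
  coverage 200 cohorts of n = 853; log-rank calibration 1000 cohorts of
  n = 200. These sizes make every simulation's Monte-Carlo error small
  relative to its acceptance band while keeping the full suite to a few
  minutes.

## Known limitations

- The engine scores one mask per case; multi-slide whole-tumor aggregation
  is out of scope.
- No reading of proprietary WSI formats or image pyramids; inputs are flat
  rasters at a fixed resolution.
- The log-rank scan reports an uncorrected maximum; treat its p value as
  exploratory.
- The Youden binarization discards patients censored before the horizon,
  which loses information relative to time-dependent ROC approaches.
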