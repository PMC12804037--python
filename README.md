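# tsrquant

Fully automated quantification of the **tumor–stroma ratio (TSR)** in colon
cancer histology, working from multi-class tissue segmentation masks — the
output of a pixel-wise segmentation backbone — rather than raw slide images.
It is aimed at digital-pathology researchers who want a standardized,
reproducible TSR score per slide and its downstream prognostic analysis,
without any human intervention at the analysis stage.

## What it computes

Within a circular region of interest (ROI) the TSR is

```
TSR = area_stroma / (area_stroma + area_tumor)
```

where the areas are pixel counts of tumor stroma and tumor epithelium; all
other tumor-associated classes (necrosis, mucin, muscle, …) are excluded
from the formula. The slide-level score is the **hotspot**: a 1-mm-diameter
ROI is slid across the tumor region on a grid with 70% overlap; every
candidate must pass

* a **composition test** — background < 10%, necrotic debris < 20%,
  mucin < 30% of the disc (strict inequalities; artifact-masked pixels
  count as background), and
* a **four-quadrant test** — tumor epithelium present in all four quadrants
  of the disc,

and the maximum TSR over eligible ROIs is the slide's score. Slides are
called *stroma-high* when TSR > 77% (the automated cut-off; the classical
visual protocol uses > 50%), and stroma-low otherwise.

The package also derives data-driven cut-offs from a cohort (Youden-index
ROC at a fixed survival horizon, and a maximally selected log-rank scan) and
runs the standard survival battery: Kaplan–Meier curves with t-year rates,
log-rank tests, univariate/adjusted Cox proportional-hazards models
(hazard ratios with 95% Wald CIs), reversed-KM median follow-up, and
chi-square association tests.

Synthetic generators produce label masks with a planted hotspot of exactly
known TSR and survival cohorts with a known threshold effect, so every stage
is testable end to end without whole-slide images.

## Worked example

```python
from tsrquant import (MaskSimParams, RoiParams, quantify_slide, simulate_mask)

sim = simulate_mask(MaskSimParams(seed=3))         # 2000x2000 px, mpp 1.0
print(f"planted hotspot TSR: {sim.truth['hotspot_tsr_percent']:.2f}%")
result, rois = quantify_slide(sim.mask, params=RoiParams())
print(f"recovered hotspot TSR: {result.tsr_percent:.2f}%  "
      f"({result.class_label}, {result.n_eligible}/{result.n_candidates} ROIs eligible)")
```

prints

```
planted hotspot TSR: 80.00%
recovered hotspot TSR: 80.00%  (stroma_high, 16/16 ROIs eligible)
```

The generator painted a disc with an exact 4:1 stroma:tumor pixel ratio; the
sliding-window engine finds it and classifies the slide as stroma-high at
the 77% cut-off. The same flow from a shell:

```bash
tsrquant simulate mask --out mask.png --truth truth.json --seed 3
tsrquant quantify --mask mask.png --out result.json --overlay rois.geojson
tsrquant simulate cohort --out cohort.tsv --truth ctruth.json --seed 3
tsrquant cutoff --cohort cohort.tsv --method youden --endpoint dfs --out cutoff.json
tsrquant survival --cohort cohort.tsv --cutoff 77 --covariates age,stage --out surv.json
```

`tsrquant roi-sweep` re-quantifies slides at 1.0/1.5/2.0-mm ROI diameters
for ROI-size comparisons.

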