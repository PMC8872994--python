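# mifquant

Quantitative multiplex-immunofluorescence (mIF) analysis and longitudinal
cohort statistics, exercised end-to-end on synthetic data with known ground
truth.

The package re-implements, as an open and tested pipeline, the workflow used
to count immune cells in tissue sections imaged on a multispectral scanner
and to relate those counts to clinical and serum variables over time:

1. **Spectral unmixing** — each pixel's observed C-channel spectrum *y* is
   decomposed over a spectral library *M* (one unit-normalized column per
   fluorophore, DAPI and tissue autofluorescence) by non-negative least
   squares, `min_a ||y − M a||²  s.t.  a ≥ 0`.
2. **Cell segmentation** — nuclei are detected on the DAPI component
   (threshold + distance-transform watershed) and the cytoplasm is simulated
   by expanding every nucleus outward by 2 µm (4 px at the default
   0.496 µm/pixel), assigning contested pixels to the nearest nucleus.
3. **Scoring** — each marker's per-cell compartment intensity is rescaled to
   [0, 1] by the 1st/99th percentiles of the whole dataset, and a cell is
   positive when the rescaled mean in the marker's primary compartment
   reaches a single dataset-wide threshold.
4. **Quantification** — positive cells per ROI as a count, a density in
   cells/mm², and a fraction of all segmented cells.
5. **Cohort statistics** — per variable, Kruskal–Wallis across timepoints
   with Dunn's post hoc (Šidák or Benjamini–Hochberg adjustment); per
   variable pair, the repeated-measures correlation
   `r = Σ x̃ỹ / √(Σ x̃² Σ ỹ²)` on within-subject-centered values
   (equivalently, the ANCOVA with subject as a factor and a common slope;
   df = N − k − 1), with a subject-level bootstrap percentile CI.

Because no patient data ship with the package, a first-class synthetic-data
module generates (a) multispectral tissue images with per-cell phenotype
ground truth and (b) a 43-subject, 3-timepoint weight-loss cohort (37
bariatric surgery, 6 low-calorie diet) with median-calibrated marker
trajectories and programmed within-subject marker–weight correlations.
Every downstream claim is tested against that ground truth.

## Who is this for

Imaging scientists and biostatisticians who want a transparent, scriptable
replacement for the closed vendor chain (unmixing → segmentation → scoring)
plus the matching longitudinal statistics, or who need a simulator with
known truth to validate an mIF analysis stack.

## Worked example

```python
import numpy as np
from mifquant import (CohortSimParams, RepeatedMeasuresCorrelation,
                      kruskal_wallis, simulate_cohort)

table, truth = simulate_cohort(CohortSimParams(), seed=7)
print(table.groupby("timepoint")[["weight", "crp", "il6", "cd8"]].median().round(4))

kw = kruskal_wallis(table["crp"], table["timepoint"])
print(f"CRP Kruskal-Wallis: H = {kw.H:.2f}, df = {kw.df}, p = {kw.p:.3g}")

table["log_crp"] = np.log(table["crp"])
model = RepeatedMeasuresCorrelation(table, x="log_crp", y="weight")
print(model.fit_bootstrap(n_boot=1000, seed=1).summary())
```

prints

```
             weight  crp  il6     cd8
timepoint
0          134.8543  5.9  4.8  0.0037
2          120.6807  4.2  1.7  0.0038
12          67.1629  1.7  1.2  0.0056

CRP Kruskal-Wallis: H = 58.19, df = 2, p = 2.31e-13

Repeated-Measures Correlation
==============================================
x                     log_crp
y                     weight
n observations        129
n subjects            43
r                     0.5199
df                    85
p-value               2.465e-07
common slope          20.62
95% bootstrap CI      [0.4022, 0.6521]  (n_boot=1000, seed=1)
==============================================
```

The medians table shows the simulated cohort hitting its configured
timepoint medians exactly (CRP falling 5.9 → 1.7 µg/ml, CD8 fraction rising
0.0037 → 0.0056 as weight falls); the Kruskal–Wallis test flags the CRP
change across timepoints; and the repeated-measures correlation estimates
the programmed within-subject CRP–weight coupling (target 0.57) with a
subject-bootstrap confidence interval.

The imaging side has the same flavour: `make_default_library` →
`place_random_cells` → `render_tissue_image` → `unmix_pixelwise` →
`segment_nuclei` / `expand_cytoplasm` → `compute_cell_stats` →
`score_cells` → `quantify`, all with the generator's truth table available
for comparison. A `mifquant` command-line tool exposes each stage
(`simulate-images`, `simulate-cohort`, `build-library`, `unmix`, `segment`,
`score`, `quantify`, `stats`, `sample-rois`) and `mifquant run --config
config.yaml` chains them end to end with a reproducibility manifest.

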