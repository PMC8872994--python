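# Methods

This note documents the models, defaults and numerical choices behind
mifquant, and what the synthetic-data generators do and do not emulate.

## Linear unmixing model

The observed pixel spectrum is modelled as a non-negative linear mixture of
component signatures: `y = M a + ε`, with `M` the spectral library
(C channels × F components, each column ≥ 0 and summing to 1) and `a ≥ 0`
the physical fluorophore abundances. Tissue autofluorescence is an ordinary
library column, not a pre-subtracted background, so it competes for signal
like any other component and cannot silently contaminate marker planes.

Per pixel we solve the NNLS problem exactly. Implementation: the
unconstrained least-squares solution is computed for all pixels in one
pseudo-inverse product; only pixels whose unconstrained optimum is
infeasible (some abundance < −10⁻¹⁰·max|y|) are re-solved with the
active-set NNLS routine. Both paths reach the same optimum; on noiseless
synthetic scenes the fast path covers every pixel and recovery is exact to
machine precision. An `ols` mode (negatives allowed) exists for oracle
comparisons only. The mean per-pixel residual norm is kept on the component
stack for QC.

Library construction: `make_default_library` models seven dye signatures as
Gaussian emission peaks at staggered channel positions (seeded jitter of
position and width) plus a broad, slowly decaying autofluorescence
signature. Eight components require at least eight channels (default 10);
construction rejects condition numbers above 10⁸. `extract_spectrum`
rebuilds a signature from a single-stain slide as the mean spectrum of the
brightest 5% of pixels (by total channel sum; the fraction is configurable
— the choice of 5% balances photon statistics against off-target pixels),
optionally background-corrected by an unstained slide's mean spectrum and
floored at zero.

## Segmentation and ring expansion

Nuclei are detected on the DAPI component plane only: light Gaussian
denoising (σ = 1 px, disabled by passing 0), Otsu threshold (or a fixed
one), Euclidean distance transform smoothed at σ = 1 px, peaks at least
3 µm apart as watershed seeds, watershed on the negated distance map, then
an area filter at 7 µm² to suppress debris. The peak-separation and
denoising defaults were chosen so that a 4 µm-radius nucleus yields exactly
one seed under up to ~10% additive noise while genuinely touching nuclei
still split; the area threshold is well below any plausible nucleus
(≈50 µm²) and above speckle.

Cytoplasm is simulated, not segmented: every nucleus is expanded outward by
2 µm, converted to whole pixels by round-half-up (4 px at 0.496 µm/pixel).
A background pixel joins the cell whose *nucleus boundary* is nearest
(Euclidean, via the distance-transform index map), so rings of neighbouring
cells partition the contested space and never overlap; the ring excludes
nucleus pixels by construction. Rings may be clipped at image borders; a
fully clipped ring keeps its cell record with ring statistics set to NaN
and a `ring_missing` flag.

Per cell and component plane we record mean/min/max/sd over nucleus and
ring pixels, plus centroid and areas in µm² (pixel count × pixel_size²).
Note the thin 2 µm ring band is the least scale-stable measurement: halving
the pixel size changes its discretized area by up to ~6% (half-pixel rim
effect), while nucleus and whole-cell areas are stable to well under 5%.

## Scoring model

Rescale bounds are the empirical 1st and 99th percentiles (linear
interpolation), computed once over the pooled dataset per marker, so equal
raw intensities render equally everywhere. By default the bounds are fitted
on per-cell compartment means — the quantity actually thresholded — rather
than raw pixels; at least 100 pooled values are required and a constant
marker is an error. A cell is positive for a marker iff the rescaled *mean*
intensity in the marker's primary compartment (ring for all six markers in
the default panel, which is cytoplasmic/membranous throughout) reaches the
marker's single dataset-wide threshold; which of the stored statistics to
threshold is configurable, mean being the default because it is the least
noise-sensitive of the four.

`suggest_threshold` (Otsu, or the crossing point of a two-component
Gaussian mixture) is advisory calibration from a set of ROIs; the stored
panel threshold remains authoritative, mirroring a pathologist-guided
workflow. Quantification reports, per ROI: positive count, density over the
full ROI extent in cells/mm², and fraction of all segmented cells; a
sample-level pooled fraction (all ROIs as one denominator) is also emitted
because per-ROI and per-sample denominators are both in use in practice.

## Synthetic images

Cells are disks: nucleus radius 4 µm by default (the geometry is not
specified by any acquisition standard; a disk is the simplest shape that
exercises watershed splitting and metric ring expansion), with the marker
abundance painted on the compartment produced by the *same* expansion
routine the pipeline uses, so generator truth and measurement share one
geometric definition. Placement is rejection sampling with a separation of
at least two radii plus two ring widths, keeping phenotype ground truth
unambiguous. The observed image is the abundance-weighted sum of library
columns plus flat autofluorescence and optional zero-mean Gaussian channel
noise, clipped at zero.

Not modelled: optical point-spread blur, chromatic registration error,
photobleaching, tile-edge artifacts, intensity gradients, or non-disk
morphology. Passing tests therefore demonstrate the correctness of the
algorithms' logic and numerics, not robustness to real optics; on real
slides the segmentation and threshold defaults would need re-tuning.

## Synthetic cohort

Defaults are the study conditions the package targets: 43 subjects (37
surgery, 6 diet — the class imbalance is kept deliberately), timepoints 0,
2 and 12 months, baseline weight median 140 kg (BMI ≈ 52 at 1.64 m),
12-month median loss 63.3 kg (surgery) / 13.0 kg (diet) with the 2-month
anchor at 15.1 / 1.7 kg, serum medians CRP 5.9/4.2/1.7 µg/ml, IL-6
4.8/1.7/1.2 pg/ml, TNF-α 29.1/31.4/25.2 pg/ml, and tissue
positive-cell-fraction medians for CD56/CD68/CD3/CD8/FOXP3/PD-1 at their
configured per-timepoint values (CD8 rising 0.0037 → 0.0056).

Weight: per-subject baseline is log-normal around the median (CV 0.12),
total loss is the arm median times a log-normal jitter (CV 0.25, capped at
75% of baseline), the trajectory linearly interpolates the 0/2/12-month
loss fractions, and a small visit-to-visit multiplicative wobble (CV 0.015,
≈2 kg) represents ordinary weight fluctuation. BMI is weight/height² with
heights N(1.64, 0.055). With noise and subject effects off the cohort is
fully deterministic and reproduces the configured losses exactly.

Markers are multiplicative log-normal around their configured medians:

    log y_it = log med(t) + b_i + β·u_it + σ_e·z_it

with subject intercepts b_i ~ N(0, 0.4²) (log scale; dispersion for the
tissue fractions is a free parameter of the generator, chosen once at a
typical biological between-subject spread), independent noise at CV 0.25
(right-skewed and positivity-preserving, consistent with variables that
fail normality checks), and u the standardized within-subject weight
deviation. The per-timepoint sample median of the stochastic part is
subtracted on the log scale, so sample medians equal the configured medians
*exactly* (hence median-monotone effect directions are guaranteed, and
calibration targets medians, matching how such cohorts are reported).

The weight-coupling coefficient β is solved per marker so that the
*expected* within-subject correlation between log marker and weight —
conditional on the realized weights, accounting for both the median
time-trend and the median-pinning recalibration — equals the configured
`rho_within` (defaults: CRP +0.57, IL-6 +0.46, CD8 −0.32, all others 0).
Median pinning makes that expectation saturate in β, so the solver scans a
signed grid for bracketing intervals and takes the root closest to zero;
an unreachable target is flagged `clamped` in the truth record rather than
silently missed. Because the target is the *expected* correlation, realized
cohorts fluctuate around it and estimator-recovery experiments remain
genuine statistical tests. The association is programmed on the log scale
(these are log-scale quantities, and the package's own plots/tests use log
markers); on the raw scale the correlation attenuates by roughly 2–10%
depending on the marker's total log-variance.

`CohortSimParams.null()` gives the matched no-effect cohort — flat medians,
all ρ = 0, near-stationary weights — used for type-I-error checks and as
the clean testbed for correlation recovery (there, any association must
come from subject-level variation, not a shared time course).

## Cohort statistics

Kruskal–Wallis uses the tie-corrected H with the chi-square reference
(k − 1 df); all-identical data return H = 0, p = 1 rather than an error.
Dunn's post hoc uses the pooled-rank z with tie correction; adjustment is
Šidák by default (Benjamini–Hochberg available), two-sided throughout, and
all three timepoint pairs are computed with the baseline pairs flagged.

The repeated-measures correlation is computed by subject-centering both
variables — algebraically identical to the subject-dummy ANCOVA estimator
(r = sign(slope)·√(SSx/(SSx+SSe)), df = N − k − 1) but O(N). Complete-case
rows are used; zero within-subject x-variance and df < 1 are explicit
errors. The bootstrap resamples *subjects* with replacement (resampled
subjects keep all visits, duplicates get distinct identities), preserving
the within-subject structure the estimator depends on; degenerate
replicates are redrawn up to 10 times then dropped with a count. The 95%
CI is the 2.5/97.5 percentile interval, seeded and deterministic.

Distribution diagnostics provide QQ data, Shapiro normality, Bartlett /
median-centered Levene / Fligner–Killeen variance tests (each group needs
≥3 observations; otherwise that test is marked not computable and the rest
run), and a Box-Cox suitability flag (MLE λ, suitable iff the transformed
values pass Shapiro at p > 0.05). Median centering for Levene was chosen
for robustness to the skewed variables these pipelines meet; mean
centering is the only other common convention.

Nonlinear mixed-effects modelling is deliberately out of scope: on data of
this shape it is convergence-fragile, which is precisely why the
repeated-measures correlation with a cluster bootstrap is the supported
route here.

## Pipeline and reproducibility

One global seed fans out to per-stage child seeds via
`SeedSequence(seed).generate_state(n_stages)` (each reduced mod 2³¹), so
stages are individually re-runnable and a re-run of the same configuration
produces byte-identical outputs (the manifest records SHA-256 checksums per
artifact, plus per-stage runtimes and cell counts). Images travel as
multichannel TIFF with JSON sidecars; tables as CSV; the panel and run
configuration as YAML.

## Problem sizes in the test and acceptance runs

Chosen as the smallest sizes at which each claim is statistically sharp:
unmixing exactness on a 256–320 px noiseless scene; segmentation recovery
on 20 ROIs of 384² px with 30–80 cells and noise up to 10% of signal;
scoring accuracy on 10 ROIs at 5% noise; correlation recovery at
n_subjects = 200 over 50–100 repeats; bootstrap coverage at n_subjects =
43, n_boot = 1000 over 50 repeats; type-I control over 50 null cohorts.

## Known limitations

- The cell model is geometric, not morphological; no overlapping or
  touching-nucleus ground truth beyond the constructed dumbbell case.
- Percentile bounds default to per-cell means; the literal raw-pixel
  reading is available but streams every component plane.
- Compartments are exclusive (ring excludes nucleus); vendor tools may
  include nuclear pixels in "cytoplasm" for cytoplasmic markers.
- KW across timepoints treats repeated observations as independent groups;
  with positive within-subject correlation this is conservative, which the
  null-cohort type-I results reflect (well below nominal α).
- The programmed correlation is exact only in expectation and on the log
  scale; raw-scale attenuation grows with a marker's log-variance.
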