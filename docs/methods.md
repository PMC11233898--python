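# Methods

`cd3path` re-implements, as a tested and fully synthetic-testable pipeline,
a digital-pathology prognosis analysis for CD3-immunostained colon-cancer
slides: region segmentation (tumour core and invasive margin), CD3⁺ cell
densities, a machine-learning tumour score built from tile features
(CD3ML), and the survival-statistics battery used to evaluate these markers
against disease-free survival (DFS) at a 60-month horizon.  This note
records the models, defaults, numerical choices and limitations.

## Imaging model

A slide is an 8-bit RGB raster with a microns-per-pixel scale (`mpp`).
Optical density is `OD = -log10((I+1)/256)` per channel; stain separation
projects the OD vector onto an H-DAB basis (Ruifrok–Johnston vectors by
default, configurable per cohort because staining platforms differ).
Negative stain concentrations are clamped at zero and the reconstruction
RMSE is reported.

Tiling uses 0-based, half-open, row-major square boxes; a partially covered
right/bottom remainder is dropped.  Default tile size is 256 px at
mpp 0.5 (≈128 µm); the desk-scale simulations use 64 px at mpp 1.0.

### The 124-feature tile bank

The tile descriptor is a frozen, versioned registry (`cd3path-124/1`) of
124 named features computed on three channels (grey luminance,
haematoxylin OD, DAB OD):

| group | count |
|---|---|
| intensity: mean, sd, skewness, excess kurtosis, min, max, deciles q10–q90 | 33 |
| Haralick texture: 13 statistics of the symmetric GLCM (32 levels, distance 1, averaged over 4 offsets) | 39 |
| gradient: Sobel magnitude mean/sd, edge density at a fixed 0.1 threshold | 9 |
| uniform local binary patterns (P=8, R=1), 10-bin histogram on grey | 10 |
| blob morphometry after Otsu on H and DAB OD: count, mean/sd area (µm²), mean eccentricity, mean extent, density per mm² | 12 |
| 2×2 quadrant grey means and sds | 8 |
| tissue fraction; saturation mean/sd; circular hue mean/sd | 5 |
| Shannon entropy (64 bins) per channel | 3 |
| box-count slope of Canny edges; granulometry (grey openings at 4 square scales) | 5 |

Degenerate inputs map to defined values: on a constant tile all
sd/variance/skewness/kurtosis-type features are 0, means equal the
constant, and blob counts are 0.  Every feature is finite for any 8-bit
RGB input (fuzz-tested).  Blob compactness uses extent (area over
bounding-box area) rather than convex-hull solidity; the convex hull costs
an order of magnitude more per tile and the two carry the same
morphometric character at lymphocyte scale.  The GLCM statistics averaged
over the four offsets, the histograms and the blob statistics are invariant
under 90° rotation; the quadrant features intentionally are not.

## Segmentation

Tiles are classified {tumour, stroma, background} by a seeded random
forest (scikit-learn, 200 trees; held-out accuracy reported at training
time).  The classifier is pluggable: the downstream contract is the label
map, not the model weights.  A background class is required to reject
glass even though only tumour tiles feed the core.

Tumour core (TC): tumour tiles are closed with a one-tile structuring
element (fills single-tile classification holes), 8-connected components
below `min_tc_area_mm2` are discarded, and the union of survivors is the
core.  Because the raster is tile-constant, the closing and the component
filter run on the tile grid and are upscaled — this is exact and ~10³×
faster than pixel-level morphology with a tile-sized element.  The minimum
surface is not a published constant; the default is 1.0 mm² (a few hundred
default-scale tiles), configurable and logged; the desk-scale pipeline
configuration lowers it to 0.01 mm² to match its far smaller slides.  An empty core is allowed
and flagged; such slides yield missing densities and are excluded from
dichotomisation.

Invasive margin (IM): the Euclidean distance band
`0 < d(·, TC) ≤ width/mpp` with width 300 µm by default, intersected with
tissue (non-background tiles).  By construction IM ∩ TC = ∅.

## Quantification

CD3⁺ detection operates on the DAB OD channel: Gaussian smoothing
(σ = 1 µm), fixed threshold 0.15 OD, components below 8 µm² removed,
touching cells split at local maxima of the distance transform
(minimum separation 4 µm) by watershed; one centre per cell, restricted to
the region mask.  These defaults are at lymphocyte scale and are recorded
with every detection.  Density is count/area (cells/mm²).

Density scores are dichotomised at the **median of each cohort**; ties go
Low (High requires strict exceedance) — deterministic and conservative.
Combined CD3 status is High only when both TC and IM are High.

## The CD3ML score

Per slide, the mean feature vector over tumour-class tiles whose box centre
lies in TC ∪ IM (the text this follows reads as including IM-zone tumour
tiles; slides with zero qualifying tiles are unanalysable).  On the
training cohort, an L1-penalised Cox model selects features:
coordinate-descent maximisation of the penalised Breslow partial
likelihood (glmnet-style IRLS outer loop, active-set inner loop with KKT
screening, warm-started lambda path of 30 values down to 0.05·λmax),
features standardised internally, coefficients reported on the original
scale.  λ is chosen by 5-fold cross-validated partial likelihood
(Verweij–Van Houwelingen), rule `min` by default (`1se` available); fold
assignment is seeded.  Development cross-checks: the path agrees with
glmnet to ~1e-4 with identical supports, and with the package's own
unpenalised Cox at λ→0 to 1e-4.

The score is the **linear predictor of an unpenalised Cox model refitted on
the selected features** (select-then-refit), centred on the training mean;
the penalised-coefficient predictor is available as an option, and is the
automatic fallback when the refit is unidentifiable (tiny cohorts).  An
empty selection yields all-zero scores and a degenerate-model flag.

Per cohort, the score is dichotomised at the cut-point maximising the
absolute standardized two-sample log-rank statistic over candidate cuts
(midpoints of consecutive unique scores) whose low-group proportion lies
strictly inside `[minprop, 1−minprop]`, minprop 0.1; ties break toward the
median.  No p-value correction is applied to the selected cut-point: only
its location is used downstream, and a maximally selected statistic does
not carry a nominal p-value (see the null-arm design below).

## Survival engine

* DFS preparation: follow-up truncated at 60 months; events after the
  horizon recoded censored at 60; events exactly at 60 retained.
* Kaplan–Meier with Greenwood variance; k-sample log-rank with the
  hypergeometric variance; for two groups the standardized statistic is
  exposed (it is the maxstat building block).
* Cox regression by Newton–Raphson with step-halving on the partial
  likelihood; Efron tie handling by default (Breslow available);
  counting-process `(start, stop]` risk sets support episode-split data;
  convergence at max|Δβ| < 1e-9; monotone likelihood raises an error
  naming the covariate.  Verified against R `survival::coxph` to 1e-7
  during development, and against lifelines in the test suite.
* Proportional-hazards diagnostic: score test for a linear association of
  Schoenfeld residuals with the left-continuous KM transform of event time
  (classic Grambsch–Therneau form with the averaged-information
  approximation V_k ≈ I/d).  R's survival ≥3 refines this with per-time
  information, so chi-squares differ by ~10%; the size of the test is
  instead verified by null simulation (400 replicates within 5% ± 2%).
* Extended Cox: piecewise-constant time-varying coefficients via episode
  splitting at configurable knots (default 22 months); one coefficient per
  interval per flagged covariate; reduces exactly to the plain fit with no
  knots; an interval without events raises an error naming it.  Agrees
  with `survSplit`+`coxph` to 1e-7.
* RMST at τ = 60: exact area under the KM step function; variance by the
  standard sum over event times of squared remaining area × Greenwood
  increments; two-group z-test on the difference.  When follow-up ends
  before τ with subjects still at risk, τ is truncated with a warning.
* Time-dependent AUC: cumulative/dynamic IPCW estimator (agrees with
  scikit-survival's `cumulative_dynamic_auc` to 1e-8; equals the empirical
  ROC AUC with no censoring) and an incident/dynamic risk-set estimator
  (per-event-time concordance averaged with weights d·S(t)).  Dispatch
  rule: PH test p ≥ 0.05 → cumulative/dynamic, otherwise incident/dynamic.
* Nested models compared by LRT; model AUCs compared over B bootstrap
  resamples of patients (B = 1000 default, seeded, unstratified) with
  Wilcoxon rank-sum tests; BH step-up adjustment (statsmodels) for
  multiplicity.
* Stratification rules: risk stage High = T4 and/or N2; 3-modality
  clinical×score stratum (High/Intermediate/Low); 4-modality N×score
  stratum.  Missing inputs propagate.

## Synthetic data

`simdata` emulates the statistical structure the analysis assumes, not the
appearance of real tissue.

**Slides.**  Tissue is the slide minus a wavy glass border; tumour blobs
are smoothed random super-ellipses (simply connected, filled), together
targeting a configurable fraction of tissue; texture differs between
tumour (high-frequency, high-variance haematoxylin field) and stroma
(smooth), so that generic tile features separate the classes without any
single engineered give-away.  CD3⁺ cells are DAB discs (radius 3 µm
default) placed by a homogeneous spatial Poisson process per region (TC /
IM / stroma) at configured densities; an optional hard-core spacing
(Matérn-II thinning) makes all cells resolvable — used by the
detection-accuracy checks, since under pure Poisson placement at
lymphocyte densities a material fraction of cells overlap and the "true
count" a detector should report is ambiguous.  The image is composed in OD
with the same H-DAB basis the imaging module inverts, plus Gaussian OD
noise.  Ground truth records masks, cell centres and exact count/area
densities.  Not emulated: nucleus morphology, scanner artefacts, stain
variation within a slide, pyramidal formats — so passing imaging tests
demonstrate correctness of the machinery, not performance on real slides.

**Cohorts.**  Feature matrix of standard-normal columns (optional
equicorrelation), sparse linear effect on the log hazard, binary risk
stage (prevalence 0.45) with a piecewise log-HR switching at a 22-month
knot, exponential baseline (inverse-CDF sampling, exact under the
piecewise model the extended Cox assumes), random exponential censoring
plus administrative censoring at 60 months.  T/N stage codes are generated
consistently with the risk-stage rule.  RNG is NumPy PCG64 throughout;
same seed ⇒ bit-identical output.

**Linked cohorts.**  A latent per-patient class (Low/High) selects both
the slide generator and the hazard contribution, so the image→score→
survival chain can be tested end to end.

## Validation battery and problem sizes

The battery (`cd3path.validation`, run by the tests and by
`scripts/acceptance.py`) uses these sizes, chosen to give stable Monte
Carlo estimates at desk scale:

* oracle equivalences on toy data (n = 6–150); maxstat versus an
  independent exhaustive scan at n = 60;
* null calibration: 400 replicates of n = 200;
* recovery: 200 replicates at n = 600 (Cox CI, true HR 2), 200 at n = 800
  (extended Cox, interval log-HRs 0.9/0.2, knot 22), 50 at n = 600,
  p = 124 (LASSO support, 5 true features at |β| = 0.5);
* imaging: 960 px slides with 32 px tiles (two for training, one held
  out); ~180 planted resolvable cells for counting;
* end-to-end: one linked training cohort of 40 patients fits the score
  once (mirroring the train/validate design of the analysis); 20
  validation replicates of 32 patients each in the effect arm and 8 in the
  null arm, on 384 px slides.  The effect arm is power-designed rather than
  tuned: demanding log-rank p < 0.01 with power ≈ 0.95 needs
  d ≈ 4(z₀.₉₉₅+z₀.₉₅)²/ln²(HR) events, ≈ 17 at a latent-class hazard ratio
  of 8, which ~32 patients supply at the configured censoring; the slide
  generators for the two classes differ five-fold in CD3 density and in
  tumour burden ("strongly separated").  Effect direction is read from the
  standardized log-rank statistic, which remains defined when perfect
  separation makes the Cox fit diverge.  In the null arm the score is split
  at its median rather than the maxstat cut: a data-optimised cut-point
  does not carry a nominal log-rank p, so uniformity of p is only a
  meaningful calibration check at a prespecified cut.

## Known limitations

* The 124-feature registry is a declared stand-in with the same character
  (intensity/texture/morphometry) as interactive-platform parameter sets;
  the exact parameters behind the original analysis are not recoverable.
* The PH diagnostic uses the averaged-information approximation; its
  chi-square differs from R survival ≥3 by ~10% although its size is
  calibrated.
* The incident/dynamic AUC is a nonparametric risk-set average, not the
  semiparametric smoothed estimator of the original toolchain.
* Scores and cut-offs are cohort-dependent by design; nothing here
  attempts cross-platform normalisation.
* Boosting-based variable selection (an alternative reported to give
  nearly identical results) is not implemented.
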