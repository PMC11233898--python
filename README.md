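# cd3path

Digital-pathology prognosis pipeline for CD3-immunostained colon-cancer
slides.  From an H-DAB RGB slide it derives the tumour core (TC) and its
300 µm invasive margin (IM), counts CD3⁺ cells per mm² in each region, and
builds a machine-learning tumour score (**CD3ML**) — the linear predictor
of a Cox model on LASSO-selected per-slide mean tile features — then runs
the survival battery used to evaluate such markers against disease-free
survival (DFS) at 60 months: Kaplan–Meier and log-rank, Cox regression
with Schoenfeld proportional-hazards diagnostics, extended Cox with
piecewise time-varying coefficients, restricted mean survival time (RMST),
time-dependent AUC, likelihood-ratio tests, bootstrap AUC comparisons and
combined clinical×score stratifications.

Because trial imaging data of this kind is not publicly deposited, the
package ships a first-class synthetic-data module: H-DAB-like slides with
exact ground truth (masks, cell centres, densities) and survival cohorts
with known sparse effects, so every stage — and the whole image→score→
survival chain — is testable without any download.

## The score in brief

Per slide, tumour-class tiles inside TC ∪ IM contribute a 124-feature mean
vector x̄ (intensity, Haralick texture, gradients, local binary patterns,
stain-blob morphometry, spatial/colour/entropy summaries — a frozen,
versioned registry).  On a training cohort with outcomes (T, δ):

1. **Selection** — L1-penalised Cox: maximise the Breslow partial
   log-likelihood minus λ‖β‖₁ by coordinate descent over a λ path; λ by
   5-fold cross-validated partial likelihood.
2. **Score** — refit an unpenalised Cox model on the selected features;
   CD3ML(x̄) = β̂ᵀ(x̄ − x̄_train).
3. **Dichotomisation** — per cohort, at the cut-point maximising the
   standardized two-sample log-rank statistic (maximally selected rank
   statistic, minprop 0.1).  CD3 densities are instead split at the cohort
   median; combined CD3 status is High only when TC **and** IM are High;
   risk stage is High for T4 and/or N2.

## Worked example

```python
import numpy as np
from cd3path import simdata, imaging, segmentation, quantify, pipeline

# a synthetic H-DAB slide with known truth
params = simdata.SlideSimParams(width_px=640, height_px=640, mpp=1.0,
                                cd3_density_tc=800, seed=7)
slide, truth = simdata.generate_slide(params)

# tile, featurise, classify, build regions
grid = imaging.tile_slide(slide, 64)
feats = imaging.compute_tile_features(slide, grid)
clf = pipeline.train_truth_tile_classifier(seed=0)      # trained on simulations
labels = segmentation.classify_tiles(clf, feats)
regions = segmentation.build_regions(labels, grid, slide.shape,
                                     mpp=1.0, min_area_mm2=0.01)

# CD3 densities
rec = quantify.quantify_slide(slide, regions)
print(f"TC {regions.tc_area_mm2:.3f} mm^2  IM {regions.im_area_mm2:.3f} mm^2")
print(f"CD3-TC {rec.cd3_tc:.0f} /mm^2   CD3-IM {rec.cd3_im:.0f} /mm^2")
print(f"truth  {truth.densities['TC']:.0f} /mm^2        "
      f"{truth.densities['IM']:.0f} /mm^2")
```

prints (machine-generated output of this exact snippet):

```
TC 0.070 mm^2  IM 0.283 mm^2
CD3-TC 704 /mm^2   CD3-IM 676 /mm^2
truth  710 /mm^2        873 /mm^2
```

i.e. the detected tumour core covers 0.070 mm² and its CD3⁺ density
(704/mm²) sits within ~1% of the planted truth (710/mm²).  The IM reading
is lower than its truth because the margin band around the *detected* core
extends into stroma, which was seeded at a lower density — exactly the
dilution a real pipeline exhibits when region boundaries are imperfect.  The full
statistical recipe on a cohort table runs as
`pipeline.run_full_analysis(cohort, AnalysisConfig(...))` and returns
hazard-ratio / RMST tables, LRT and time-dependent-AUC tables and KM
curves, every comparison dispatched between Cox/log-rank and RMST by the
proportional-hazards rule.

A thin CLI mirrors the stages: `cd3path simulate | segment | quantify |
score | survfit | run-all`.

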