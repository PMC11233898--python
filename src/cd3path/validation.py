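"""Validation battery: oracle equivalences, calibration, recovery, imaging,
end-to-end linked simulation, structural rules.

These suites are the package's own evidence that each stage does what it
claims: exact agreement with independent oracles for the closed-form
statistics, simulation calibration of test sizes, parameter-recovery and
support-recovery rates, imaging accuracy against ground truth, and the full
image-to-survival pipeline on linked synthetic cohorts.  They are run by the
test suite and by ``scripts/acceptance.py``.

All randomness is derived from a single seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pipeline, quantify, scoring, segmentation, simdata, survstats
from .features import FEATURE_NAMES
from .imaging import compute_tile_features, tile_slide

__all__ = [
    "oracle_suite",
    "calibration_suite",
    "recovery_suite",
    "imaging_suite",
    "endtoend_suite",
    "structural_suite",
]


def _child_seeds(seed, n):
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# 1. statistical oracle equivalences
# ---------------------------------------------------------------------------

def _brute_force_cox_beta(x, time, event, lo=-4.0, hi=4.0):
    def pl(beta):
        ll = 0.0
        for i in np.nonzero(event)[0]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(lo, hi, 2001)
    for _ in range(6):
        vals = [pl(b) for b in grid]
        j = int(np.argmax(vals))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
        grid = np.linspace(lo, hi, 101)
    return grid[int(np.argmax([pl(b) for b in grid]))]


def _maxstat_scan_oracle(score, time, event, minprop=0.1):
    """Independent exhaustive scan with a from-first-principles log-rank z."""
    best_z, best_m = -np.inf, None
    med = np.median(score)
    uniq = np.unique(score)
    for m in (uniq[:-1] + uniq[1:]) / 2:
        prop = (score <= m).mean()
        if not (minprop < prop < 1 - minprop):
            continue
        grp = score > m
        o_e, v = 0.0, 0.0
        for u in np.unique(time[event == 1]):
            at = time >= u
            n = at.sum()
            d = ((time == u) & (event == 1)).sum()
            n1 = (at & grp).sum()
            d1 = ((time == u) & (event == 1) & grp).sum()
            o_e += d1 - d * n1 / n
            if n > 1:
                v += d * (n - d) * n1 * (n - n1) / ((n - 1) * n**2)
        if v <= 0:
            continue
        z = abs(o_e) / np.sqrt(v)
        if z > best_z + 1e-15 or (abs(z - best_z) <= 1e-15 and
                                  abs(m - med) < abs(best_m - med)):
            best_z, best_m = z, m
    return best_z, best_m


def oracle_suite(seed: int = 0) -> dict:
    """Exact-agreement checks of the closed-form statistics."""
    out = {}
    # Cox beta on a 6-subject no-ties dataset vs partial-likelihood grid search
    x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
    time = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 9.0])
    event = np.array([1, 1, 0, 1, 1, 1])
    fit = survstats.fit_cox(x[:, None], time, event)
    out["cox_beta_vs_bruteforce_abs_err"] = float(
        abs(fit.beta[0] - _brute_force_cox_beta(x, time, event))
    )
    # log-rank == Cox score test (binary covariate, Breslow ties)
    rng = np.random.default_rng(seed + 1)
    n = 150
    g = (rng.random(n) < 0.5).astype(float)
    te = rng.exponential(1 / (0.04 * np.exp(0.5 * g)))
    tc = np.minimum(rng.exponential(80, n), 60.0)
    t = np.minimum(te, tc)
    e = (te <= tc).astype(int)
    chi_lr, _, _ = survstats.logrank_test(t, e, g)
    chi_sc, _, _ = survstats.cox_score_test(g[:, None], t, e, ties="breslow")
    out["logrank_vs_cox_score_abs_err"] = float(abs(chi_lr - chi_sc))
    # RMST == exact step-function integral (midpoint rule on jump grid)
    a, _ = survstats.rmst(t, e, 50.0)
    km = survstats.km_estimate(t, e)
    brk = np.concatenate([[0.0], km.times[km.times <= 50.0], [50.0]])
    mids = (brk[:-1] + brk[1:]) / 2
    exact = float((km.evaluate(mids) * np.diff(brk)).sum())
    out["rmst_vs_step_integral_abs_err"] = float(abs(a - exact))
    # maxstat cut equals the exhaustive-scan oracle
    rng = np.random.default_rng(seed + 2)
    score = rng.standard_normal(60)
    te = rng.exponential(1 / (0.08 * np.exp(0.9 * score)))
    t2 = np.minimum(te, 30.0)
    e2 = (te <= 30.0).astype(int)
    cut = scoring.maxstat_cutoff(score, t2, e2, minprop=0.1)
    z_star, m_star = _maxstat_scan_oracle(score, t2, e2, minprop=0.1)
    out["maxstat_cut_abs_err"] = float(abs(cut.cutoff - m_star))
    out["maxstat_stat_abs_err"] = float(abs(abs(cut.statistic) - z_star))
    # BH step-up on the textbook example
    adj = survstats.bh_adjust([0.01, 0.02, 0.03, 0.04])
    out["bh_adjusted_max_abs_err"] = float(np.max(np.abs(adj - 0.04)))
    return out


# ---------------------------------------------------------------------------
# 2. null calibration
# ---------------------------------------------------------------------------

def calibration_suite(seed: int = 0, reps: int = 400, n: int = 200,
                      alpha: float = 0.05) -> dict:
    """Empirical size of log-rank, LRT, PH test and RMST difference under
    the null (no group effect, no covariate effect, PH holds)."""
    seeds = _child_seeds(seed, reps)
    hits = dict(logrank=0, lrt=0, ph=0, rmst=0)
    for s in seeds:
        p = simdata.CohortSimParams(n_patients=n, baseline_hazard=0.02,
                                    censor_random_rate=0.005, seed=s,
                                    n_features=2)
        tab, _ = simdata.generate_cohort(p)
        t = tab["time_months"].to_numpy()
        e = tab["event"].to_numpy()
        rng = np.random.default_rng(s + 1)
        g = (rng.random(n) < 0.5).astype(int)
        hits["logrank"] += survstats.logrank_test(t, e, g)[2] < alpha
        X = tab[["f001", "f002"]].to_numpy()
        red = survstats.fit_cox(X[:, :1], t, e)
        full = survstats.fit_cox(X, t, e)
        hits["lrt"] += survstats.lrt_nested(red, full)[2] < alpha
        fg = survstats.fit_cox(g.astype(float)[:, None], t, e)
        z = survstats.schoenfeld_ph_test(fg)
        hits["ph"] += float(z.loc[z["term"] == "GLOBAL", "p"].iloc[0]) < alpha
        hits["rmst"] += survstats.rmst_compare(t, e, g, tau=60).p < alpha
    return {f"size_{k}": v / reps for k, v in hits.items()}


# ---------------------------------------------------------------------------
# 3. recovery
# ---------------------------------------------------------------------------

def recovery_suite(seed: int = 0, cox_reps: int = 200, ext_reps: int = 200,
                   lasso_reps: int = 50) -> dict:
    """CI coverage for Cox (true HR 2) and the extended Cox piecewise
    effect (0.9 / 0.2 at knot 22), and LASSO support recovery
    (5 true features at |beta| = 0.5 among 124, n = 600)."""
    out = {}
    # plain Cox coverage at n = 600
    seeds = _child_seeds(seed + 1, cox_reps)
    cover = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        x = (rng.random(600) < 0.5).astype(float)
        te = rng.exponential(1 / (0.02 * np.exp(np.log(2) * x)))
        tc = np.minimum(rng.exponential(120, 600), 60.0)
        t = np.minimum(te, tc)
        e = (te <= tc).astype(int)
        fit = survstats.fit_cox(x[:, None], t, e)
        lo = fit.beta[0] - 1.959963984540054 * fit.se[0]
        hi = fit.beta[0] + 1.959963984540054 * fit.se[0]
        cover += lo <= np.log(2) <= hi
    out["cox_ci_coverage"] = cover / cox_reps

    # extended Cox interval-coefficient coverage at n = 800
    seeds = _child_seeds(seed + 2, ext_reps)
    cov_early = cov_late = 0
    for s in seeds:
        p = simdata.CohortSimParams(
            n_patients=800, n_features=1, risk_beta_early=0.9,
            risk_beta_late=0.2, knot_months=22.0, baseline_hazard=0.02,
            risk_stage_prevalence=0.5, seed=s,
        )
        tab, truth = simdata.generate_cohort(p)
        xr = truth["risk_high"].astype(float)
        ext = survstats.fit_extended_cox(
            pd.DataFrame({"risk": xr}), tab["time_months"].to_numpy(),
            tab["event"].to_numpy(), tv_covariates=["risk"], knots=[22.0],
        )
        f = ext.fit
        for j, target, acc in ((0, 0.9, "early"), (1, 0.2, "late")):
            lo = f.beta[j] - 1.959963984540054 * f.se[j]
            hi = f.beta[j] + 1.959963984540054 * f.se[j]
            if lo <= target <= hi:
                if acc == "early":
                    cov_early += 1
                else:
                    cov_late += 1
    out["extcox_coverage_early"] = cov_early / ext_reps
    out["extcox_coverage_late"] = cov_late / ext_reps

    # LASSO support recovery
    seeds = _child_seeds(seed + 3, lasso_reps)
    hits = 0
    support = (0, 10, 30, 60, 100)
    for s in seeds:
        p = simdata.CohortSimParams(
            n_patients=600, n_features=124, true_support=support,
            true_beta=(0.5,) * 5, baseline_hazard=0.01,
            censor_random_rate=0.003, seed=s,
        )
        tab, _ = simdata.generate_cohort(p)
        fcols = [f"f{j + 1:03d}" for j in range(124)]
        fit = scoring.fit_lasso_cox(
            tab[fcols], tab["time_months"].to_numpy(),
            tab["event"].to_numpy(), seed=s, n_lambda=25,
            lambda_min_ratio=0.1,
        )
        sel = {fit.feature_names.index(name) for name in fit.selected}
        hits += len(sel & set(support)) >= 4
    out["lasso_support_recovery_rate"] = hits / lasso_reps
    return out


# ---------------------------------------------------------------------------
# 4. imaging
# ---------------------------------------------------------------------------

def imaging_suite(seed: int = 0) -> dict:
    """Classifier accuracy, tumour-core IoU, margin-band geometry,
    CD3 count error and the density worked example, on synthetic slides."""
    tile = 32

    def make(seed_i):
        p = simdata.SlideSimParams(
            width_px=960, height_px=960, mpp=1.0, tumour_blob_count=2,
            tumour_fraction_target=0.35, seed=seed_i,
        )
        slide, truth = simdata.generate_slide(p)
        grid = tile_slide(slide, tile)
        feats = compute_tile_features(slide, grid)
        labels = []
        for r, c, _ in grid.boxes():
            tum = truth.tumour_mask[r * tile:(r + 1) * tile,
                                    c * tile:(c + 1) * tile].mean()
            tis = truth.tissue_mask[r * tile:(r + 1) * tile,
                                    c * tile:(c + 1) * tile].mean()
            labels.append("tumour" if tum > 0.5
                          else ("background" if tis < 0.3 else "stroma"))
        return slide, truth, grid, feats, np.asarray(labels)

    s_train = _child_seeds(seed + 4, 3)
    trains = [make(s) for s in s_train[:2]]
    merged = pd.concat([t[3].table for t in trains], ignore_index=True)
    from .imaging import TileFeatureTable

    feats_all = TileFeatureTable(table=merged, tile_size_px=tile)
    labels_all = np.concatenate([t[4] for t in trains])
    clf = segmentation.train_tile_classifier(feats_all, labels_all, seed=seed)
    out = {"tile_classifier_holdout_accuracy": clf.holdout_accuracy}

    slide, truth, grid, feats, labels = make(s_train[2])
    lm = segmentation.classify_tiles(clf, feats)
    regions = segmentation.build_regions(lm, grid, slide.shape, mpp=1.0,
                                         min_area_mm2=0.01)
    inter = (regions.tc_mask & truth.tumour_mask).sum()
    union = (regions.tc_mask | truth.tumour_mask).sum()
    out["tc_iou"] = float(inter / union)

    # margin-band geometry on the detected core
    from scipy import ndimage

    im = segmentation.build_invasive_margin(regions.tc_mask, width_um=300.0,
                                            mpp=1.0)
    d = ndimage.distance_transform_edt(~regions.tc_mask)
    out["im_band_max_distance_px"] = float(d[im].max())
    out["im_band_min_distance_px"] = float(d[im].min())

    # CD3 count error at ~200 planted, resolvable cells
    p = simdata.SlideSimParams(
        width_px=640, height_px=640, mpp=1.0, tumour_blob_count=1,
        tumour_fraction_target=0.18, cd3_density_tc=4000.0,
        cd3_density_im=0.0, cd3_density_stroma=0.0,
        min_cell_spacing_um=7.0, seed=_child_seeds(seed + 5, 1)[0],
    )
    slide2, truth2 = simdata.generate_slide(p)
    det = quantify.detect_cd3_cells(slide2, truth2.tumour_mask)
    n_true = len(truth2.cell_centres)
    out["cd3_count_rel_err_pct"] = float(
        100.0 * abs(det.count - n_true) / n_true
    )
    # density arithmetic worked example: 500 cells on 0.5 mm^2
    out["density_worked_example_cells_per_mm2"] = quantify.compute_density(
        500, 2e6 * 0.5**2 / 1e6
    )
    return out


# ---------------------------------------------------------------------------
# 5. end-to-end linked simulation
# ---------------------------------------------------------------------------

def endtoend_suite(seed: int = 0, effect_reps: int = 20,
                   null_reps: int = 8) -> dict:
    """Image-to-survival pipeline on linked cohorts.

    Effect arm: latent class drives slide appearance and hazard; the score
    strata should separate survival (log-rank p < 0.01, HR > 1).  Null arm:
    identical slide parameters and no hazard effect; the median-split score
    strata log-rank p should be uniform.
    """
    fit, clf, _ = pipeline.fit_linked_training(seed=seed + 50_000)
    res = [pipeline.evaluate_linked_validation(s, fit, clf, separated=True)
           for s in _child_seeds(seed + 6, effect_reps)]
    ok = [r for r in res if not r["degenerate"]]
    out = {
        "e2e_n_selected_features": len(fit.selected),
        "e2e_effect_reject_rate": float(np.mean(
            [(r["p"] < 0.01) and r.get("high_worse", False) for r in res]
        )),
        "e2e_effect_median_p": float(np.median([r["p"] for r in ok]))
        if ok else np.nan,
    }
    null = [pipeline.evaluate_linked_validation(s, fit, clf, separated=False,
                                                cut="median")
            for s in _child_seeds(seed + 7, null_reps)]
    pvals = np.array([r["p"] for r in null if not r["degenerate"]])
    out["e2e_null_reps"] = int(pvals.size)
    out["e2e_null_frac_below_0p05"] = float((pvals < 0.05).mean()) \
        if pvals.size else np.nan
    from scipy import stats as spstats

    out["e2e_null_ks_uniform_p"] = float(
        spstats.kstest(pvals, "uniform").pvalue
    ) if pvals.size >= 5 else np.nan
    return out


# ---------------------------------------------------------------------------
# 6. structural rules
# ---------------------------------------------------------------------------

def structural_suite(seed: int = 0) -> dict:
    """The printed stratification definitions and the 70/30 split sizes."""
    out = {}
    out["combine_cd3_ok"] = float(
        quantify.combine_cd3("High", "High") == "CD3_High"
        and quantify.combine_cd3("High", "Low") == "CD3_Other"
        and quantify.combine_cd3("Low", "High") == "CD3_Other"
        and quantify.combine_cd3("Low", "Low") == "CD3_Other"
    )
    out["risk_stage_ok"] = float(
        survstats.classify_risk_stage("T4", "N1") == "High"
        and survstats.classify_risk_stage("T3", "N1") == "Low"
        and survstats.classify_risk_stage("T1", "N2") == "High"
        and survstats.classify_risk_stage("T4", "N2") == "High"
    )
    out["three_modality_ok"] = float(
        survstats.combine_clinical_cd3ml("High", "High") == "High"
        and survstats.combine_clinical_cd3ml("Low", "High") == "Intermediate"
        and survstats.combine_clinical_cd3ml("High", "Low") == "Intermediate"
        and survstats.combine_clinical_cd3ml("Low", "Low") == "Low"
    )
    out["four_modality_ok"] = float(
        survstats.combine_n_cd3ml("N1", "Low") == "N1/CD3ML_Low"
        and survstats.combine_n_cd3ml("N2", "High") == "N2/CD3ML_High"
    )
    tr, va = pipeline.split_cohort(pd.DataFrame({"pid": range(989)}),
                                   frac=0.7, seed=seed)
    out["split_training_n"] = len(tr)
    out["split_validation_n"] = len(va)
    return out
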