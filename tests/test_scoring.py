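"""Score construction: slide means, LASSO-Cox, linear predictor, maxstat."""

import numpy as np
import pandas as pd
import pytest

from cd3path import scoring, segmentation, survstats
from cd3path.features import FEATURE_NAMES
from cd3path.imaging import TileFeatureTable
from cd3path.scoring import (
    cd3ml_score,
    dichotomise_cutoff,
    fit_lasso_cox,
    maxstat_cutoff,
    slide_mean_features,
)


def _surv_sample(seed=3, n=200, beta=(0.7, -0.5, 0.4), p=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    b = np.zeros(p)
    b[: len(beta)] = beta
    te = rng.exponential(1 / (0.05 * np.exp(X @ b)))
    tc = rng.exponential(30, n)
    return X, np.minimum(te, tc), (te <= tc).astype(int)


# ---------------------------------------------------------------------------
# slide mean features
# ---------------------------------------------------------------------------

def _toy_profile_inputs(vectors, labels, centres_in_region):
    """Construct aligned tile features / labels / regions by hand."""
    s = 32
    n = len(vectors)
    rows = []
    for i, v in enumerate(vectors):
        rows.append({"row": 0, "col": i, **dict(zip(FEATURE_NAMES, v))})
    feats = TileFeatureTable(table=pd.DataFrame(rows), tile_size_px=s)
    lab = segmentation.TileLabelMap(
        table=pd.DataFrame({"row": [0] * n, "col": range(n), "label": labels})
    )
    mask = np.zeros((s, s * n), dtype=bool)
    for i, inside in enumerate(centres_in_region):
        if inside:
            mask[:, i * s:(i + 1) * s] = True
    regions = segmentation.RegionSet(
        tc_mask=mask, im_mask=np.zeros_like(mask), mpp=1.0
    )
    return feats, lab, regions


def test_slide_mean_single_tile():
    v = np.arange(124, dtype=float)
    feats, lab, regions = _toy_profile_inputs([v], ["tumour"], [True])
    prof = slide_mean_features(feats, lab, regions)
    assert prof.n_tiles_used == 1
    assert np.array_equal(prof.values, v)


def test_slide_mean_averages_and_excludes_stroma():
    v = np.zeros(124)
    w = np.ones(124)
    distractor = np.full(124, 99.0)
    feats, lab, regions = _toy_profile_inputs(
        [v, w, distractor], ["tumour", "tumour", "stroma"],
        [True, True, True],
    )
    prof = slide_mean_features(feats, lab, regions)
    assert prof.n_tiles_used == 2
    assert np.allclose(prof.values, 0.5)


def test_slide_mean_excludes_tiles_outside_regions():
    v = np.zeros(124)
    w = np.ones(124)
    feats, lab, regions = _toy_profile_inputs(
        [v, w], ["tumour", "tumour"], [True, False]
    )
    prof = slide_mean_features(feats, lab, regions)
    assert prof.n_tiles_used == 1
    assert np.allclose(prof.values, 0.0)


def test_slide_mean_zero_qualifying_tiles_missing():
    v = np.zeros(124)
    feats, lab, regions = _toy_profile_inputs([v], ["stroma"], [True])
    prof = slide_mean_features(feats, lab, regions)
    assert not prof.valid and prof.values is None


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------

def test_lasso_full_shrinkage_at_large_lambda():
    X, t, e = _surv_sample()
    fit = fit_lasso_cox(X, t, e, lambda_grid=[10.0])
    assert fit.degenerate
    assert np.all(fit.coef_penalised == 0)


def test_lasso_zero_lambda_matches_unpenalised_cox():
    X, t, e = _surv_sample(n=200, p=3)
    fit = fit_lasso_cox(X, t, e, lambda_grid=[1e-9])
    ref = survstats.fit_cox(X, t, e, ties="breslow")
    sel = [fit.feature_names.index(s) for s in fit.selected]
    assert np.allclose(fit.coef_penalised[sel], ref.beta[sel], atol=1e-4)


def test_lasso_path_support_monotone_in_lambda():
    X, t, e = _surv_sample(seed=5, n=150, p=8)
    lambdas = np.geomspace(0.5, 0.001, 25)
    fit = fit_lasso_cox(X, t, e, lambda_grid=lambdas)
    sizes = (fit.path_betas != 0).sum(axis=1)
    # support grows (weakly) as lambda decreases along the path
    assert np.all(np.diff(sizes) >= -1)  # allow rare swaps
    assert sizes[0] <= sizes[-1]


def test_lasso_matches_sksurv_coxnet_support():
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X, t, e = _surv_sample(seed=7, n=200, p=6)
    alphas = [0.05, 0.02]
    m = CoxnetSurvivalAnalysis(alphas=alphas, l1_ratio=1.0, tol=1e-9)
    m.fit(X, Surv.from_arrays(event=e.astype(bool), time=t))
    sd = X.std(axis=0)
    mine = scoring._lasso_path((X - X.mean(0)) / sd, t, e, alphas) / sd
    theirs = m.coef_.T
    assert np.array_equal(mine[1] != 0, theirs[1] != 0)
    assert np.allclose(mine[1], theirs[1], atol=0.02)


def test_lasso_deterministic_given_seed():
    X, t, e = _surv_sample(seed=9, n=120, p=10)
    f1 = fit_lasso_cox(X, t, e, seed=4)
    f2 = fit_lasso_cox(X, t, e, seed=4)
    assert f1.selected == f2.selected
    assert np.array_equal(f1.coef_penalised, f2.coef_penalised)


def test_lasso_drops_constant_columns_with_warning():
    X, t, e = _surv_sample(n=120, p=4)
    X[:, 3] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_lasso_cox(X, t, e, lambda_grid=[0.01])
    assert fit.coef_penalised[3] == 0.0


def test_lasso_requires_events():
    X, t, _ = _surv_sample(n=50, p=3)
    with pytest.raises(ValueError):
        fit_lasso_cox(X, t, np.zeros(50, int))


def test_lasso_null_selection_modest_with_1se():
    sizes = []
    for rep in range(10):
        rng = np.random.default_rng(rep + 100)
        X = rng.standard_normal((150, 20))
        t = rng.exponential(20, 150)
        e = (rng.random(150) < 0.7).astype(int)
        fit = fit_lasso_cox(X, t, e, choice_rule="1se", seed=rep)
        sizes.append(len(fit.selected))
    assert np.mean(sizes) <= 20 * 0.2


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------

def test_score_empty_selection_is_zero():
    X, t, e = _surv_sample()
    fit = fit_lasso_cox(X, t, e, lambda_grid=[10.0])
    assert fit.degenerate
    assert np.all(cd3ml_score(fit, X) == 0.0)


def test_score_single_feature_is_centred_feature():
    rng = np.random.default_rng(12)
    n = 300
    x0 = rng.standard_normal(n)
    X = np.column_stack([x0, rng.standard_normal(n) * 0.01])
    te = rng.exponential(1 / (0.05 * np.exp(1.0 * x0)))
    t = np.minimum(te, 40.0)
    e = (te <= 40).astype(int)
    fit = fit_lasso_cox(X, t, e, lambda_grid=[0.15])
    assert fit.selected == ["f001"]
    score = cd3ml_score(fit, X)
    beta = fit.coef_refit[0]
    assert np.allclose(score, beta * (x0 - x0.mean()), atol=1e-12)


def test_score_invariant_to_unselected_feature_rescaling():
    X, t, e = _surv_sample(seed=21, n=200, p=5)
    fit = fit_lasso_cox(X, t, e, lambda_grid=[0.08])
    assert 0 < len(fit.selected) < 5
    score1 = cd3ml_score(fit, X)
    X2 = X.copy()
    unsel = [j for j in range(5)
             if fit.feature_names[j] not in fit.selected]
    X2[:, unsel] = X2[:, unsel] * 7.5 + 3.0
    score2 = cd3ml_score(fit, X2)
    assert np.array_equal(np.argsort(score1), np.argsort(score2))
    assert np.allclose(score1, score2)


def test_score_missing_feature_errors():
    X, t, e = _surv_sample(n=120, p=3)
    fit = fit_lasso_cox(pd.DataFrame(X, columns=["a", "b", "c"]), t, e,
                        lambda_grid=[0.01])
    with pytest.raises(KeyError):
        cd3ml_score(fit, pd.DataFrame(X[:, :2], columns=["a", "b"]))


# ---------------------------------------------------------------------------
# maximally selected cut-point
# ---------------------------------------------------------------------------

def _maxstat_oracle(score, time, event, minprop):
    """Independent exhaustive scan with a from-scratch log-rank z."""
    best = (-np.inf, None)
    med = np.median(score)
    for m in (np.unique(score)[:-1] + np.unique(score)[1:]) / 2:
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
        key = (z, -abs(m - med))
        if key > (best[0], -abs(best[1] - med) if best[1] is not None else -np.inf):
            best = (z, m)
    return best


def test_maxstat_matches_exhaustive_oracle():
    rng = np.random.default_rng(31)
    n = 60
    score = rng.standard_normal(n)
    te = rng.exponential(1 / (0.08 * np.exp(0.9 * score)))
    t = np.minimum(te, 30.0)
    e = (te <= 30.0).astype(int)
    cut = maxstat_cutoff(score, t, e, minprop=0.1)
    z_star, m_star = _maxstat_oracle(score, t, e, 0.1)
    assert cut.cutoff == pytest.approx(m_star)
    assert abs(cut.statistic) == pytest.approx(z_star, abs=1e-9)


def test_maxstat_finds_planted_threshold():
    # events early for score > 14, late otherwise -> cut in (14, 15]
    score = np.arange(1.0, 21.0)
    time = np.where(score > 14, 5.0, 50.0) + 0.1 * score
    event = np.ones(20, int)
    cut = maxstat_cutoff(score, time, event, minprop=0.1)
    assert 14 < cut.cutoff <= 15


def test_maxstat_negation_symmetry():
    rng = np.random.default_rng(41)
    score = rng.standard_normal(40)
    te = rng.exponential(1 / (0.1 * np.exp(0.8 * score)))
    e = np.ones(40, int)
    c1 = maxstat_cutoff(score, te, e)
    c2 = maxstat_cutoff(-score, te, e)
    assert c2.cutoff == pytest.approx(-c1.cutoff)
    assert abs(c2.statistic) == pytest.approx(abs(c1.statistic), abs=1e-9)


def test_maxstat_statistic_consistent_with_logrank():
    rng = np.random.default_rng(51)
    score = rng.standard_normal(50)
    te = rng.exponential(1 / (0.1 * np.exp(0.5 * score)))
    e = np.ones(50, int)
    cut = maxstat_cutoff(score, te, e)
    grp = np.where(score > cut.cutoff, "High", "Low")
    z = survstats.logrank_z(te, e, grp)
    assert abs(cut.statistic) == pytest.approx(abs(z), abs=1e-9)


def test_maxstat_degenerate_inputs():
    with pytest.raises(ValueError):
        maxstat_cutoff(np.ones(10), np.arange(1.0, 11), np.ones(10, int))
    with pytest.raises(ValueError):
        maxstat_cutoff(np.arange(10.0), np.arange(1.0, 11), np.ones(10, int),
                       minprop=0.5)


# ---------------------------------------------------------------------------
# cut-off dichotomisation
# ---------------------------------------------------------------------------

def test_cutoff_tie_goes_low():
    labels = dichotomise_cutoff([1.0, 2.0, 3.0], 2.0)
    assert list(labels) == ["Low", "Low", "High"]


def test_cutoff_monotone_transform_invariance():
    rng = np.random.default_rng(61)
    score = rng.standard_normal(50)
    cut = 0.3
    l1 = dichotomise_cutoff(score, cut)
    l2 = dichotomise_cutoff(np.exp(score), np.exp(cut))
    assert np.array_equal(l1, l2)


def test_cutoff_per_cohort_equals_single_cohort_runs():
    rng = np.random.default_rng(71)
    s1, s2 = rng.standard_normal(30), rng.standard_normal(30) + 2
    c1, c2 = 0.1, 2.3
    joint = np.concatenate([
        dichotomise_cutoff(s1, c1), dichotomise_cutoff(s2, c2)
    ])
    merged_scores = np.concatenate([s1, s2])
    cohorts = np.array(["a"] * 30 + ["b"] * 30)
    out = np.empty(60, dtype=object)
    for name, cut in (("a", c1), ("b", c2)):
        m = cohorts == name
        out[m] = dichotomise_cutoff(merged_scores[m], cut)
    assert np.array_equal(out.astype(str), joint)
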