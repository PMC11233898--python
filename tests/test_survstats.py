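"""Survival engine: oracle equivalences, closed forms, cross-library checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cd3path import survstats

# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t_in,e_in,t_out,e_out",
    [(72.0, 1, 60.0, 0),      # event beyond the horizon -> censored at 60
     (59.0, 1, 59.0, 1),
     (60.0, 1, 60.0, 1),      # events exactly at the horizon are retained
     (60.0, 0, 60.0, 0),
     (75.0, 0, 60.0, 0)],
)
def test_prepare_dfs_horizon_rule(t_in, e_in, t_out, e_out):
    t, e = survstats.prepare_dfs([t_in], [e_in])
    assert t[0] == t_out and e[0] == e_out


def test_prepare_dfs_rejects_negative_times():
    with pytest.raises(survstats.DataError):
        survstats.prepare_dfs([-1.0], [1])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_all_censored_is_unity():
    km = survstats.km_estimate([5, 10, 15], [0, 0, 0])
    assert km.times.size == 0
    assert np.all(km.evaluate([1, 50]) == 1.0)


def test_km_closed_form_single_event():
    # n=3, one event at t=3, no earlier censoring: S(3+) = 2/3
    km = survstats.km_estimate([3, 8, 9], [1, 0, 0])
    assert km.evaluate(3.0)[0] == pytest.approx(2 / 3)


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 60)
    km = survstats.km_estimate(t, np.ones(60, int))
    grid = np.linspace(0.1, 30, 40)
    emp = np.array([(t > g).mean() for g in grid])
    assert np.allclose(km.evaluate(grid), emp)


def test_km_greenwood_se_matches_bootstrap(toy_cohort):
    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    km = survstats.km_estimate(t, e)
    t_ref = np.quantile(t[e == 1], 0.5)
    i = np.searchsorted(km.times, t_ref, side="right") - 1
    rng = np.random.default_rng(1)
    boots = []
    for _ in range(400):
        idx = rng.integers(0, t.size, t.size)
        boots.append(survstats.km_estimate(t[idx], e[idx]).evaluate(km.times[i])[0])
    assert km.se[i] == pytest.approx(np.std(boots), rel=0.15)


def test_km_matches_lifelines(toy_cohort):
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(toy_cohort["time"], toy_cohort["event"])
    km = survstats.km_estimate(toy_cohort["time"], toy_cohort["event"])
    theirs = kmf.survival_function_at_times(km.times).to_numpy()
    assert np.allclose(km.surv, theirs, atol=1e-10)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_zero():
    t = np.array([2.0, 4, 6, 8, 2, 4, 6, 8])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    g = np.repeat([0, 1], 4)
    chi2, df, p = survstats.logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_logrank_matches_permutation_oracle():
    # hand-built n=8 dataset; oracle: permutation distribution of the
    # two-sample statistic computed from first principles
    t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
    g = np.array([0, 0, 1, 0, 1, 1, 0, 1])

    def observed_minus_expected(grp):
        o_e = 0.0
        v = 0.0
        for u in np.unique(t[e == 1]):
            at = t >= u
            n = at.sum()
            d = ((t == u) & (e == 1)).sum()
            n1 = (at & (grp == 1)).sum()
            d1 = ((t == u) & (e == 1) & (grp == 1)).sum()
            o_e += d1 - d * n1 / n
            if n > 1:
                v += d * (n - d) * n1 * (n - n1) / ((n - 1) * n**2)
        return o_e, v

    o_e, v = observed_minus_expected(g)
    chi2, _, _ = survstats.logrank_test(t, e, g)
    assert chi2 == pytest.approx(o_e**2 / v, abs=1e-9)
    # permutation reference distribution of (O-E)^2/V
    from itertools import combinations

    stats_perm = []
    for idx in combinations(range(8), int(g.sum())):
        gp = np.zeros(8)
        gp[list(idx)] = 1
        oe, vv = observed_minus_expected(gp)
        stats_perm.append(oe**2 / vv)
    p_perm = np.mean(np.asarray(stats_perm) >= chi2 - 1e-12)
    _, _, p_asym = survstats.logrank_test(t, e, g)
    # asymptotic p within a loose band of the exact permutation p at n=8
    assert abs(p_perm - p_asym) < 0.25


def test_logrank_equals_cox_score_test_binary(toy_cohort):
    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    x = toy_cohort["x"].to_numpy()
    chi2_lr, _, _ = survstats.logrank_test(t, e, x)
    chi2_sc, _, _ = survstats.cox_score_test(x[:, None], t, e, ties="breslow")
    assert chi2_lr == pytest.approx(chi2_sc, abs=1e-6)


def test_logrank_matches_lifelines(toy_cohort):
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(toy_cohort["time"], toy_cohort["x"],
                                    toy_cohort["event"])
    chi2, _, p = survstats.logrank_test(toy_cohort["time"],
                                        toy_cohort["event"],
                                        toy_cohort["x"])
    assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)


def test_logrank_requires_two_groups():
    with pytest.raises(survstats.DataError):
        survstats.logrank_test([1, 2, 3], [1, 1, 0], [0, 0, 0])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def _brute_force_cox_beta(x, time, event, lo=-4.0, hi=4.0):
    """Grid-search maximiser of the hand-coded partial likelihood."""

    def pl(beta):
        ll = 0.0
        for i in np.nonzero(event)[0]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(lo, hi, 2001)
    for _ in range(6):               # coarse-to-fine refinement
        vals = [pl(b) for b in grid]
        j = int(np.argmax(vals))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
        grid = np.linspace(lo, hi, 101)
    return grid[int(np.argmax([pl(b) for b in grid]))]


def test_cox_beta_matches_brute_force_toy():
    # 6 subjects, no ties
    x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
    time = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 9.0])
    event = np.array([1, 1, 0, 1, 1, 1])
    fit = survstats.fit_cox(x[:, None], time, event)
    assert fit.beta[0] == pytest.approx(
        _brute_force_cox_beta(x, time, event), abs=1e-6
    )
    assert fit.loglik >= fit.loglik_null


def test_cox_exchangeable_groups_beta_zero():
    t = np.tile([1.0, 2, 3, 4, 5], 2)
    e = np.tile([1, 1, 0, 1, 1], 2)
    x = np.repeat([0.0, 1.0], 5)
    fit = survstats.fit_cox(x[:, None], t, e)
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)


def test_cox_matches_lifelines_multivariate():
    rng = np.random.default_rng(5)
    n = 120
    X = rng.standard_normal((n, 3))
    te = rng.exponential(1 / (0.05 * np.exp(X @ [0.5, -0.3, 0.2])))
    tc = rng.exponential(25, n)
    t = np.minimum(te, tc)
    e = (te <= tc).astype(int)
    fit = survstats.fit_cox(X, t, e)
    from lifelines import CoxPHFitter

    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["T"] = t
    df["E"] = e
    cph = CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(fit.beta, cph.params_[["a", "b", "c"]], atol=1e-5)
    assert np.allclose(fit.se, cph.standard_errors_[["a", "b", "c"]],
                       atol=1e-5)


def test_cox_errors():
    t = np.array([1.0, 2, 3, 4])
    with pytest.raises(survstats.DataError):
        survstats.fit_cox(np.ones((4, 1)), t, [1, 0, 1, 0])     # constant col
    with pytest.raises(survstats.DataError):
        survstats.fit_cox(np.arange(4.0)[:, None], t, [0, 0, 0, 0])  # no events
    # monotone likelihood: perfect separation
    x = np.array([0.0, 0, 1, 1])
    with pytest.raises(survstats.ConvergenceError):
        survstats.fit_cox(x[:, None], np.array([1.0, 2, 10, 12]),
                          np.array([1, 1, 1, 1]))


def test_cox_breslow_vs_efron_differ_only_with_ties(toy_cohort):
    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    x = toy_cohort["x"].to_numpy()[:, None]
    f1 = survstats.fit_cox(x, t, e, ties="efron")
    f2 = survstats.fit_cox(x, t, e, ties="breslow")
    assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-9)  # no ties here


# ---------------------------------------------------------------------------
# Schoenfeld PH test
# ---------------------------------------------------------------------------

def test_ph_test_close_to_lifelines(toy_cohort):
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = toy_cohort.rename(columns={"time": "T", "event": "E"})
    cph = CoxPHFitter().fit(df, "T", "E")
    theirs = proportional_hazard_test(cph, df, time_transform="km")
    fit = survstats.fit_cox(toy_cohort[["x"]], toy_cohort["time"],
                            toy_cohort["event"])
    mine = survstats.schoenfeld_ph_test(fit)
    chi2 = float(mine.loc[mine["term"] == "x", "chi2"].iloc[0])
    assert chi2 == pytest.approx(float(theirs.summary["test_statistic"].iloc[0]),
                                 rel=0.15)


def test_ph_test_detects_strong_time_varying_effect():
    from cd3path import simdata

    hits = 0
    for rep in range(20):
        p = simdata.CohortSimParams(
            n_patients=600, n_features=1, risk_beta_early=0.8,
            risk_beta_late=-0.8, baseline_hazard=0.02,
            risk_stage_prevalence=0.5, seed=rep,
        )
        tab, truth = simdata.generate_cohort(p)
        x = truth["risk_high"].astype(float)[:, None]
        fit = survstats.fit_cox(x, tab["time_months"], tab["event"])
        z = survstats.schoenfeld_ph_test(fit)
        hits += float(z.loc[z["term"] == "GLOBAL", "p"].iloc[0]) < 0.05
    assert hits / 20 >= 0.8


def test_ph_test_degenerate_input_errors():
    fit = survstats.fit_cox(np.array([[0.3], [1.2], [0.1]]),
                            [1.0, 2.0, 3.0], [1, 0, 0])
    with pytest.raises(survstats.DataError):
        survstats.schoenfeld_ph_test(fit)


# ---------------------------------------------------------------------------
# extended Cox
# ---------------------------------------------------------------------------

def test_extended_cox_reduces_to_plain(toy_cohort):
    plain = survstats.fit_cox(toy_cohort[["x"]], toy_cohort["time"],
                              toy_cohort["event"])
    ext = survstats.fit_extended_cox(toy_cohort[["x"]], toy_cohort["time"],
                                     toy_cohort["event"], tv_covariates=[],
                                     knots=[22])
    assert ext.fit.beta[0] == pytest.approx(plain.beta[0], abs=1e-9)


def test_extended_cox_matches_lifelines_time_varying(toy_cohort):
    from lifelines import CoxTimeVaryingFitter

    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    ext = survstats.fit_extended_cox(toy_cohort[["x"]], t, e,
                                     tv_covariates=["x"], knots=[15.0])
    subj, start, stop, ev = survstats.episode_split(t, e, [15.0])
    x = toy_cohort["x"].to_numpy()[subj]
    df = pd.DataFrame({
        "id": subj, "start": start, "stop": stop, "ev": ev,
        "xa": x * (start < 15.0), "xb": x * (start >= 15.0),
    })
    ctv = CoxTimeVaryingFitter().fit(df, id_col="id", start_col="start",
                                     stop_col="stop", event_col="ev")
    assert np.allclose(ext.fit.beta, ctv.params_[["xa", "xb"]], atol=1e-5)


def test_extended_cox_empty_interval_errors():
    t = np.array([1.0, 2, 3, 4, 5, 6])
    e = np.array([1, 1, 1, 1, 1, 1])
    x = np.array([0.0, 1, 0, 1, 0, 1])
    with pytest.raises(survstats.DataError, match="interval"):
        survstats.fit_extended_cox(pd.DataFrame({"x": x}), t, e,
                                   tv_covariates=["x"], knots=[50.0])


def test_extended_cox_knot_validation(toy_cohort):
    with pytest.raises(survstats.DataError):
        survstats.fit_extended_cox(toy_cohort[["x"]], toy_cohort["time"],
                                   toy_cohort["event"], tv_covariates=["x"],
                                   knots=[-3.0])


# ---------------------------------------------------------------------------
# RMST
# ---------------------------------------------------------------------------

def test_rmst_no_events_is_tau():
    a, s = survstats.rmst(np.full(10, 60.0), np.zeros(10, int), 60.0)
    assert a == 60.0


def test_rmst_all_events_at_30():
    a, _ = survstats.rmst(np.full(8, 30.0), np.ones(8, int), 60.0)
    assert a == pytest.approx(30.0)


def test_rmst_equals_riemann_sum(toy_cohort):
    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    tau = 50.0
    a, _ = survstats.rmst(t, e, tau)
    km = survstats.km_estimate(t, e)
    # midpoint rule on the jump-aligned grid is exact for step functions
    brk = np.concatenate([[0.0], km.times[km.times <= tau], [tau]])
    mids = (brk[:-1] + brk[1:]) / 2
    riemann = float((km.evaluate(mids) * np.diff(brk)).sum())
    assert a == pytest.approx(riemann, abs=1e-9)


def test_rmst_difference_antisymmetric(toy_cohort):
    g = np.where(toy_cohort["x"] == 1, "A", "B")
    r1 = survstats.rmst_compare(toy_cohort["time"], toy_cohort["event"], g,
                                tau=50)
    g2 = np.where(toy_cohort["x"] == 1, "B", "A")
    r2 = survstats.rmst_compare(toy_cohort["time"], toy_cohort["event"], g2,
                                tau=50)
    assert r1.difference == pytest.approx(-r2.difference, abs=1e-12)
    assert r1.p == pytest.approx(r2.p, abs=1e-12)


def test_rmst_matches_lifelines_point_estimate(toy_cohort):
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    a, _ = survstats.rmst(toy_cohort["time"], toy_cohort["event"], 50.0)
    kmf = KaplanMeierFitter().fit(toy_cohort["time"], toy_cohort["event"])
    assert a == pytest.approx(restricted_mean_survival_time(kmf, t=50.0),
                              abs=1e-9)


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

def test_td_auc_perfect_score():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 300)
    e = np.ones(300, int)
    score = -t                      # perfect rank of event time
    for est in ("cumulative_dynamic", "incident_dynamic"):
        res = survstats.td_auc(score, t, e, np.median(t), estimator=est)
        assert res.auc >= 0.99


def test_td_auc_random_score_near_half():
    rng = np.random.default_rng(3)
    aucs = []
    for rep in range(10):
        t = rng.exponential(10, 500)
        e = np.ones(500, int)
        s = rng.standard_normal(500)
        aucs.append(survstats.td_auc(s, t, e, np.median(t)).auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_td_auc_no_censoring_equals_roc(toy_cohort):
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    score = rng.standard_normal(200)
    t = rng.exponential(10 * np.exp(-score))
    e = np.ones(200, int)
    t_eval = float(np.median(t))
    mine = survstats.td_auc(score, t, e, t_eval).auc
    assert mine == pytest.approx(roc_auc_score(t <= t_eval, score), abs=1e-9)


def test_td_auc_matches_sksurv(toy_cohort):
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    score = toy_cohort["x"].to_numpy() + 0.01 * np.arange(len(t))
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    theirs, _ = cumulative_dynamic_auc(y, y, score, [30.0])
    mine = survstats.td_auc(score, t, e, 30.0)
    assert mine.auc == pytest.approx(theirs[0], abs=1e-8)


def test_td_auc_dispatch_rule(toy_cohort):
    t = toy_cohort["time"].to_numpy()
    e = toy_cohort["event"].to_numpy()
    s = toy_cohort["x"].to_numpy()
    assert survstats.td_auc_auto(s, t, e, 30.0, ph_p=0.5).estimator == \
        "cumulative_dynamic"
    assert survstats.td_auc_auto(s, t, e, 30.0, ph_p=0.01).estimator == \
        "incident_dynamic"


def test_td_auc_no_events_errors():
    with pytest.raises(survstats.DataError):
        survstats.td_auc([1.0, 2.0], [5.0, 6.0], [0, 0], 4.0)


# ---------------------------------------------------------------------------
# LRT, bootstrap comparison, BH
# ---------------------------------------------------------------------------

def test_lrt_identical_models(toy_cohort):
    f = survstats.fit_cox(toy_cohort[["x"]], toy_cohort["time"],
                          toy_cohort["event"])
    chi2, df, p = survstats.lrt_nested(f, f)
    assert chi2 == pytest.approx(0.0, abs=1e-10) and p == 1.0


def test_lrt_rejects_non_nested(toy_cohort):
    rng = np.random.default_rng(0)
    d = toy_cohort.assign(z=rng.standard_normal(len(toy_cohort)))
    f1 = survstats.fit_cox(d[["x"]], d["time"], d["event"])
    f2 = survstats.fit_cox(d[["z"]], d["time"], d["event"])
    with pytest.raises(survstats.DataError):
        survstats.lrt_nested(f1, f2)


def test_lrt_power_for_true_covariate():
    rng = np.random.default_rng(6)
    rejections = 0
    for _ in range(30):
        n = 600
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        te = rng.exponential(1 / (0.03 * np.exp(0.7 * x)))
        t = np.minimum(te, 60.0)
        e = (te <= 60.0).astype(int)
        d = pd.DataFrame({"x": x, "z": z})
        red = survstats.fit_cox(d[["z"]], t, e)
        full = survstats.fit_cox(d[["z", "x"]], t, e)
        rejections += survstats.lrt_nested(red, full)[2] < 0.05
    assert rejections / 30 >= 0.9


def test_bootstrap_auc_same_seed_identical(toy_cohort):
    rng = np.random.default_rng(8)
    scores = {"a": toy_cohort["x"].to_numpy() + 0.1 * rng.standard_normal(160),
              "b": rng.standard_normal(160)}
    d1, p1 = survstats.bootstrap_auc_compare(
        scores, toy_cohort["time"], toy_cohort["event"], 30.0, B=25, seed=3)
    d2, p2 = survstats.bootstrap_auc_compare(
        scores, toy_cohort["time"], toy_cohort["event"], 30.0, B=25, seed=3)
    assert d1.equals(d2) and p1.equals(p2)


def test_bootstrap_auc_self_comparison(toy_cohort):
    s = toy_cohort["x"].to_numpy() + 0.01 * np.arange(160)
    dist, _ = survstats.bootstrap_auc_compare(
        {"m1": s, "m2": s.copy()}, toy_cohort["time"], toy_cohort["event"],
        30.0, B=20, seed=0)
    assert np.median(dist["m1"] - dist["m2"]) == 0.0


def test_bootstrap_auc_detects_informative_covariate():
    rng = np.random.default_rng(9)
    n = 300
    x = rng.standard_normal(n)
    te = rng.exponential(1 / (0.04 * np.exp(0.9 * x)))
    t = np.minimum(te, 60.0)
    e = (te <= 60.0).astype(int)
    noise = rng.standard_normal(n)
    dist, pmat = survstats.bootstrap_auc_compare(
        {"base": noise, "with_x": noise * 0.1 + x}, t, e, 30.0, B=100, seed=1)
    assert dist["with_x"].median() > dist["base"].median()
    assert pmat.loc["base", "with_x"] < 0.05


def test_bootstrap_auc_parameter_validation(toy_cohort):
    with pytest.raises(survstats.DataError):
        survstats.bootstrap_auc_compare(
            {"a": toy_cohort["x"], "b": toy_cohort["x"]},
            toy_cohort["time"], toy_cohort["event"], 30.0, B=1)


@pytest.mark.parametrize(
    "pvals,expected",
    [([0.02], [0.02]),
     ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04])],
)
def test_bh_adjust_closed_form(pvals, expected):
    assert np.allclose(survstats.bh_adjust(pvals), expected)


def test_bh_adjust_dominates_raw():
    rng = np.random.default_rng(10)
    p = rng.random(50)
    assert np.all(survstats.bh_adjust(p) >= p - 1e-12)


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(survstats.DataError):
        survstats.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# stratification rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t,n,expected",
                         [("T4", "N1", "High"), ("T3", "N1", "Low"),
                          ("T4", "N2", "High"), ("T1", "N2", "High"),
                          ("T2", "N1", "Low")])
def test_risk_stage_rule(t, n, expected):
    assert survstats.classify_risk_stage(t, n) == expected


def test_risk_stage_rejects_unknown_codes():
    with pytest.raises(survstats.DataError):
        survstats.classify_risk_stage("T5", "N1")


@pytest.mark.parametrize("c,s,expected",
                         [("High", "High", "High"),
                          ("Low", "High", "Intermediate"),
                          ("High", "Low", "Intermediate"),
                          ("Low", "Low", "Low")])
def test_three_modality_mapping(c, s, expected):
    assert survstats.combine_clinical_cd3ml(c, s) == expected


def test_three_modality_propagates_missing():
    out = survstats.combine_clinical_cd3ml(["High", np.nan], ["High", "Low"])
    assert out[0] == "High" and pd.isna(out[1])


def test_four_modality_mapping_partitions():
    n = np.array(["N1", "N2", "N1", "N2"], dtype=object)
    s = np.array(["Low", "High", "High", "Low"], dtype=object)
    out = survstats.combine_n_cd3ml(n, s)
    assert out[0] == "N1/CD3ML_Low" and out[1] == "N2/CD3ML_High"
    assert len(set(out)) == 4
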