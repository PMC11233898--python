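"""Survival-statistics engine.

Implements the estimators used throughout the prognosis analysis: Kaplan-Meier
with Greenwood variance, the k-sample log-rank test, Cox proportional-hazards
regression (Efron or Breslow tie handling, counting-process risk sets), the
Schoenfeld-residual proportional-hazards diagnostic, an extended Cox model
with piecewise-constant time-varying coefficients, restricted mean survival
time (RMST) comparison, time-dependent AUC (cumulative/dynamic IPCW and
incident/dynamic risk-set estimators), likelihood-ratio tests for nested
models, bootstrap AUC comparison, Benjamini-Hochberg adjustment, and the
clinical stratification rules (risk stage, combined strata).

Times are in months throughout; disease-free survival is evaluated at a
60-month horizon (`prepare_dfs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvCurve",
    "CoxFit",
    "ExtendedCoxFit",
    "RmstResult",
    "TdAucResult",
    "prepare_dfs",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "cox_loglik",
    "schoenfeld_ph_test",
    "fit_extended_cox",
    "rmst",
    "rmst_compare",
    "td_auc",
    "lrt_nested",
    "bootstrap_auc_compare",
    "bh_adjust",
    "classify_risk_stage",
    "combine_clinical_cd3ml",
    "combine_n_cd3ml",
]

DFS_HORIZON_MONTHS = 60.0


class DataError(ValueError):
    """Raised when input data violate a documented contract."""


class ConvergenceError(RuntimeError):
    """Raised when a partial-likelihood maximisation fails to converge."""


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_dfs(time, event, horizon: float = DFS_HORIZON_MONTHS):
    """Apply the evaluation-horizon rule to (time, event) pairs.

    Follow-up beyond ``horizon`` is administratively censored at the horizon;
    events occurring exactly at the horizon are retained as events.

    Returns ``(time, event)`` as float/int arrays.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise DataError("time and event must have the same shape")
    if np.any(time < 0):
        raise DataError("negative survival times")
    out_t = np.minimum(time, horizon)
    out_e = np.where(time > horizon, 0, event)
    return out_t, out_e


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.ndim != 1 or time.shape != event.shape:
        raise DataError("time and event must be 1-d and aligned")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise DataError("times must be finite and non-negative")
    if not np.all(np.isin(event, [0, 1])):
        raise DataError("event indicator must be 0/1")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvCurve:
    """Product-limit survival curve with Greenwood standard errors."""

    times: np.ndarray          # unique event times, ascending
    surv: np.ndarray           # S(t) just after each event time
    se: np.ndarray             # Greenwood SE of S(t)
    n_risk: np.ndarray
    n_event: np.ndarray
    n: int

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step evaluation S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones(t.shape)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "surv": self.surv,
                "se": self.se,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


def km_estimate(time, event) -> SurvCurve:
    """Kaplan-Meier estimate with Greenwood variance."""
    time, event = _check_surv(time, event)
    if time.size == 0:
        raise DataError("empty sample")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    n = t.size
    n_risk = np.empty(uniq.size)
    n_event = np.empty(uniq.size)
    for i, u in enumerate(uniq):
        n_risk[i] = np.sum(t >= u)
        n_event[i] = np.sum((t == u) & (e == 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - n_event / n_risk
        surv = np.cumprod(frac)
        gw = np.cumsum(n_event / (n_risk * np.maximum(n_risk - n_event, 1e-300)))
        se = surv * np.sqrt(gw)
    se = np.where(np.isfinite(se), se, 0.0)
    return SurvCurve(times=uniq, surv=surv, se=se, n_risk=n_risk,
                     n_event=n_event, n=n)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(time, event, group):
    """k-sample log-rank test.

    Returns ``(chi2, df, p)``; for two groups the result also carries the
    standardized statistic ``z = (O1 - E1) / sqrt(V11)`` as a fourth element
    accessible via :func:`logrank_z`.
    """
    chi2, df, p, _ = _logrank_full(time, event, group)
    return chi2, df, p


def logrank_z(time, event, group) -> float:
    """Standardized two-sample log-rank statistic (first group minus expected)."""
    _, _, _, z = _logrank_full(time, event, group)
    if z is None:
        raise DataError("standardized statistic defined for two groups only")
    return z


def _logrank_full(time, event, group):
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise DataError("group must align with time")
    levels = np.unique(group)
    k = levels.size
    if k < 2:
        raise DataError("log-rank requires at least two groups")
    if event.sum() == 0:
        raise DataError("log-rank requires at least one event")
    gidx = np.searchsorted(levels, group)
    uniq = np.unique(time[event == 1])
    m = uniq.size
    # at-risk counts per group at each event time via sorted searchsorted
    n_g = np.empty((m, k))
    d_g = np.empty((m, k))
    for g in range(k):
        tg = np.sort(time[gidx == g])
        n_g[:, g] = tg.size - np.searchsorted(tg, uniq, side="left")
        tge = np.sort(time[(gidx == g) & (event == 1)])
        lo = np.searchsorted(tge, uniq, side="left")
        hi = np.searchsorted(tge, uniq, side="right")
        d_g[:, g] = hi - lo
    n_tot = n_g.sum(axis=1)
    d_tot = d_g.sum(axis=1)
    O = d_g.sum(axis=0)
    E = (d_tot / n_tot)[:, None] * n_g
    E = E.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n_tot > 1,
                     d_tot * (n_tot - d_tot) / (n_tot - 1) / n_tot**2, 0.0)
    # V = sum_u c_u * (diag(n_g n_tot) - outer(n_g, n_g))
    V = np.einsum("u,ug,uh->gh", c, n_g, n_g) * -1.0
    V[np.diag_indices(k)] += np.einsum("u,ug->g", c * n_tot, n_g)
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    z = None
    if k == 2 and V[0, 0] > 0:
        z = float((O[0] - E[0]) / np.sqrt(V[0, 0]))
    return chi2, df, p, z


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    ``beta`` are log hazard ratios; confidence intervals are Wald
    ``exp(beta +/- 1.96 SE)``.  Schoenfeld residuals (one row per event,
    ordered by event time) are stored for the proportional-hazards test.
    """

    terms: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    information: np.ndarray
    schoenfeld_times: np.ndarray
    schoenfeld: np.ndarray
    schoenfeld_v: np.ndarray                 # per-death risk-set covariance
    converged: bool
    n_iter: int
    # raw data retained for diagnostics / downstream tests
    _time: np.ndarray | None = field(default=None, repr=False)
    _event: np.ndarray | None = field(default=None, repr=False)

    @property
    def hr(self):
        return np.exp(self.beta)

    @property
    def ci(self):
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def zscores(self):
        return self.beta / self.se

    @property
    def pvalues(self):
        return 2 * stats.norm.sf(np.abs(self.zscores))

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues,
            }
        )


def _as_design(X, terms=None):
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if terms is None:
            terms = [f"x{j}" for j in range(X.shape[1])]
    return X, list(terms)


def _cox_quantities(beta, X, time, event, start, ties):
    """Partial log-likelihood, score, information, Schoenfeld residuals.

    Counting-process risk sets: subject i is at risk at event time t iff
    ``start_i < t <= time_i``.  Efron or Breslow handling of tied events.
    With right-censored data and no tied event times (the common continuous
    case) a fully vectorised suffix-sum path is used.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()          # numerical stabilisation; PL invariant
    w = np.exp(eta)
    uniq, tie_counts = np.unique(time[event == 1], return_counts=True)
    if (start.max() == 0 and p <= 25 and uniq.size
            and tie_counts.max() == 1):
        return _cox_quantities_fast(eta, w, X, time, event, uniq)
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    sch_t = []
    sch_r = []
    sch_v = []          # per-death risk-set covariance V(t_k)
    for u in uniq:
        at_risk = (start < u) & (time >= u)
        deaths = (time == u) & (event == 1)
        d = int(deaths.sum())
        wr = w[at_risk]
        Xr = X[at_risk]
        S0 = wr.sum()
        S1 = wr @ Xr
        S2 = (wr[:, None] * Xr).T @ Xr
        wd = w[deaths]
        Xd = X[deaths]
        sum_eta_d = eta[deaths].sum()
        if ties == "breslow" or d == 1:
            loglik += sum_eta_d - d * np.log(S0)
            xbar = S1 / S0
            score += Xd.sum(axis=0) - d * xbar
            vbar = S2 / S0 - np.outer(xbar, xbar)
            info += d * vbar
            mean_xbar = xbar
        elif ties == "efron":
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            mean_xbar = np.zeros(p)
            vbar = np.zeros((p, p))
            loglik += sum_eta_d
            for l in range(d):
                f = l / d
                denom = S0 - f * s0d
                num1 = S1 - f * s1d
                num2 = S2 - f * s2d
                xbar = num1 / denom
                loglik -= np.log(denom)
                score += Xd.sum(axis=0) / d - xbar
                v_l = num2 / denom - np.outer(xbar, xbar)
                info += v_l
                vbar += v_l / d
                mean_xbar += xbar / d
        else:
            raise ValueError(f"unknown ties method {ties!r}")
        # Schoenfeld residual per death: x_i - (averaged) risk-set mean
        for xi in Xd:
            sch_t.append(u)
            sch_r.append(xi - mean_xbar)
            sch_v.append(vbar)
    sch_t = np.asarray(sch_t)
    sch_r = np.asarray(sch_r) if sch_r else np.zeros((0, p))
    sch_v = np.asarray(sch_v) if sch_v else np.zeros((0, p, p))
    return loglik, score, info, sch_t, sch_r, sch_v


def _cox_quantities_fast(eta, w, X, time, event, uniq):
    """Vectorised no-ties path: suffix sums over the time-sorted sample."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    w_s = w[order]
    X_s = X[order]
    W0 = np.cumsum(w_s[::-1])[::-1]
    W1 = np.cumsum((w_s[:, None] * X_s)[::-1], axis=0)[::-1]
    outer = np.einsum("i,ij,ik->ijk", w_s, X_s, X_s)
    W2 = np.cumsum(outer[::-1], axis=0)[::-1]
    pos = np.searchsorted(t_s, uniq, side="left")
    S0 = W0[pos]
    S1 = W1[pos]
    S2 = W2[pos]
    xbar = S1 / S0[:, None]
    V = S2 / S0[:, None, None] - np.einsum("ij,ik->ijk", xbar, xbar)
    # event rows in event-time order (times are unique)
    ev_sorted = np.nonzero(event[order] == 1)[0]
    Xe = X_s[ev_sorted]
    eta_e = eta[order][ev_sorted]
    loglik = float(eta_e.sum() - np.log(S0).sum())
    resid = Xe - xbar
    score = resid.sum(axis=0)
    info = V.sum(axis=0)
    return loglik, score, info, uniq.copy(), resid, V


def cox_loglik(beta, X, time, event, start=None, ties="efron") -> float:
    """Cox partial log-likelihood at ``beta`` (no fitting)."""
    X, _ = _as_design(X)
    time, event = _check_surv(time, event)
    start = np.zeros_like(time) if start is None else np.asarray(start, float)
    ll, *_ = _cox_quantities(np.asarray(beta, float), X, time, event, start, ties)
    return float(ll)


def fit_cox(X, time, event, ties: str = "efron", start=None,
            max_iter: int = 60, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson maximisation of the Cox partial likelihood.

    Parameters
    ----------
    X : array or DataFrame, shape (n, p)
    time, event : survival outcome; with ``start`` given, risk sets are the
        counting-process intervals ``(start, time]``.
    ties : ``"efron"`` (default) or ``"breslow"``.

    Raises
    ------
    DataError
        on constant columns or absence of events.
    ConvergenceError
        if Newton-Raphson does not converge (e.g. monotone likelihood),
        naming the runaway covariate.
    """
    X, terms = _as_design(X)
    time, event = _check_surv(time, event)
    start = np.zeros_like(time) if start is None else np.asarray(start, float)
    n, p = X.shape
    n_events = int(event.sum())
    if n_events == 0:
        raise DataError("no events: Cox model cannot be fitted")
    sd = X.std(axis=0)
    const = np.where(sd == 0)[0]
    if const.size:
        raise DataError(f"constant column(s): {[terms[j] for j in const]}")
    if n_events < p:
        raise DataError(f"fewer events ({n_events}) than covariates ({p})")

    beta = np.zeros(p)
    ll_null, *_ = _cox_quantities(beta, X, time, event, start, ties)
    ll_prev = ll_null
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, info, *_ = _cox_quantities(beta, X, time, event, start, ties)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step halving if likelihood would decrease
        new_beta = beta + step
        ll_new, *_ = _cox_quantities(new_beta, X, time, event, start, ties)
        halves = 0
        while ll_new < ll_prev - 1e-12 and halves < 30:
            step *= 0.5
            new_beta = beta + step
            ll_new, *_ = _cox_quantities(new_beta, X, time, event, start, ties)
            halves += 1
        beta = new_beta
        ll_prev = ll_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        j = int(np.argmax(np.abs(beta)))
        raise ConvergenceError(
            f"Cox fit did not converge (possible monotone likelihood, "
            f"covariate {terms[j]!r}, |beta|={abs(beta[j]):.2f})"
        )
    ll, score, info, sch_t, sch_r, sch_v = _cox_quantities(beta, X, time, event, start, ties)
    cov = np.linalg.inv(info)
    return CoxFit(
        terms=terms,
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        loglik=float(ll),
        loglik_null=float(ll_null),
        ties=ties,
        n=n,
        n_events=n_events,
        information=info,
        schoenfeld_times=sch_t,
        schoenfeld=sch_r,
        schoenfeld_v=sch_v,
        converged=converged,
        n_iter=it,
        _time=time,
        _event=event,
    )


def cox_score_test(X, time, event, ties="breslow") -> tuple:
    """Score test of beta = 0 (chi2, df, p); equals log-rank for one binary
    covariate with Breslow ties."""
    X, _ = _as_design(X)
    time, event = _check_surv(time, event)
    start = np.zeros_like(time)
    p = X.shape[1]
    _, score, info, *_ = _cox_quantities(np.zeros(p), X, time, event, start, ties)
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, p, float(stats.chi2.sf(chi2, p))


# ---------------------------------------------------------------------------
# Schoenfeld proportional-hazards diagnostic
# ---------------------------------------------------------------------------

def schoenfeld_ph_test(fit: CoxFit, transform: str = "km") -> pd.DataFrame:
    """Score test for proportional hazards from scaled Schoenfeld residuals.

    Tests, per covariate and globally, for a linear association of the
    Schoenfeld residuals with a transform of event time (default: left-
    continuous Kaplan-Meier transform ``g(t) = 1 - KM(t-)``).  Returns a frame
    with rows per covariate plus a ``GLOBAL`` row (columns chi2, df, p).
    """
    if fit.schoenfeld.shape[0] < 2:
        raise DataError("PH test needs at least two events")
    r = fit.schoenfeld                      # (d, p) residuals at event times
    d, p = r.shape
    t = fit.schoenfeld_times
    if transform == "km":
        if fit._time is None:
            raise DataError("fit lacks stored outcome data")
        km = km_estimate(fit._time, fit._event)
        # left-continuous survival just before each event time
        idx = np.searchsorted(km.times, t, side="left") - 1
        surv_minus = np.where(idx >= 0, km.surv[np.maximum(idx, 0)], 1.0)
        g = 1.0 - surv_minus
    elif transform == "identity":
        g = t.astype(float)
    elif transform == "rank":
        g = stats.rankdata(t)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()
    gg = float(g @ g)
    if gg <= 0:
        raise DataError("degenerate time transform (all events tied)")
    # score test for theta = 0 in beta(t) = beta + theta g(t), with the
    # exact per-event-time risk-set covariances V_k:
    #   u = sum g_k r_k,  C = sum g_k^2 V_k - (sum g_k V_k) I^{-1} (sum g_k V_k)
    V = fit.schoenfeld_v                    # (d, p, p)
    u = g @ r                               # (p,)
    sum_g2V = np.tensordot(g**2, V, axes=1)
    sum_gV = np.tensordot(g, V, axes=1)
    C = sum_g2V - sum_gV @ np.linalg.solve(fit.information, sum_gV)
    per_chi2 = u**2 / np.maximum(np.diag(C), 1e-300)
    global_chi2 = float(u @ np.linalg.solve(C, u))
    out = pd.DataFrame(
        {
            "term": fit.terms + ["GLOBAL"],
            "chi2": np.concatenate([per_chi2, [global_chi2]]),
            "df": [1] * p + [p],
        }
    )
    out["p"] = stats.chi2.sf(out["chi2"], out["df"])
    return out


# ---------------------------------------------------------------------------
# extended Cox with piecewise-constant time-varying coefficients
# ---------------------------------------------------------------------------

@dataclass
class ExtendedCoxFit:
    """Cox fit on episode-split data with interval-specific coefficients.

    ``fit`` is the underlying counting-process :class:`CoxFit`; terms for a
    time-varying covariate ``v`` with knots ``[22]`` are named
    ``v@(0,22]`` and ``v@(22,inf]``.
    """

    fit: CoxFit
    tv_covariates: list
    knots: list

    def summary(self) -> pd.DataFrame:
        return self.fit.summary()


def episode_split(time, event, knots):
    """Split each subject's follow-up at the knots (counting-process rows).

    Returns ``(subject_index, start, stop, event_row)`` arrays.
    """
    time, event = _check_surv(time, event)
    knots = sorted(float(k) for k in knots)
    subj, start, stop, ev = [], [], [], []
    bounds = [0.0] + knots + [np.inf]
    for i, (t, e) in enumerate(zip(time, event)):
        for a, b in zip(bounds[:-1], bounds[1:]):
            if t <= a:
                break
            s = min(t, b)
            subj.append(i)
            start.append(a)
            stop.append(s)
            ev.append(int(e) if s == t else 0)
    return (np.asarray(subj), np.asarray(start, float),
            np.asarray(stop, float), np.asarray(ev, int))


def fit_extended_cox(X, time, event, tv_covariates, knots=(22.0,),
                     ties: str = "efron") -> ExtendedCoxFit:
    """Extended Cox model: time-varying coefficients, piecewise-constant.

    For each covariate named in ``tv_covariates`` one coefficient is
    estimated per inter-knot interval; remaining covariates keep a single
    time-constant coefficient.  With an empty ``tv_covariates`` (or no
    knots) the result equals :func:`fit_cox`.

    Raises DataError when some interval contains no events (coefficient
    unidentifiable), naming the interval.
    """
    Xd, terms = _as_design(X)
    time, event = _check_surv(time, event)
    knots = sorted(float(k) for k in knots)
    for k in knots:
        if not (0 < k < np.inf):
            raise DataError(f"knot {k} outside (0, inf)")
    tv = list(tv_covariates)
    unknown = [v for v in tv if v not in terms]
    if unknown:
        raise DataError(f"unknown time-varying covariate(s): {unknown}")
    if not tv or not knots:
        fit = fit_cox(Xd, time, event, ties=ties)
        fit.terms = terms
        return ExtendedCoxFit(fit=fit, tv_covariates=[], knots=list(knots))

    subj, start, stop, ev = episode_split(time, event, knots)
    bounds = [0.0] + knots + [np.inf]
    intervals = list(zip(bounds[:-1], bounds[1:]))
    cols = []
    names = []
    for j, name in enumerate(terms):
        col = Xd[subj, j]
        if name in tv:
            for a, b in intervals:
                in_int = (start >= a) & (start < b)
                label = f"{name}@({a:g},{'inf' if np.isinf(b) else format(b, 'g')}]"
                cols.append(col * in_int)
                names.append(label)
                d_int = ev[in_int & (col != 0)].sum() if np.any(in_int) else 0
                if ev[in_int].sum() == 0:
                    raise DataError(f"no events in interval ({a:g},{b:g}]")
                del d_int
        else:
            cols.append(col)
            names.append(name)
    Xs = np.column_stack(cols)
    fit = fit_cox(pd.DataFrame(Xs, columns=names), stop, ev, ties=ties, start=start)
    return ExtendedCoxFit(fit=fit, tv_covariates=tv, knots=list(knots))


# ---------------------------------------------------------------------------
# RMST
# ---------------------------------------------------------------------------

@dataclass
class RmstResult:
    tau: float
    groups: list
    rmst: np.ndarray
    se: np.ndarray
    difference: float | None = None
    diff_se: float | None = None
    p: float | None = None

    def ci(self, level=0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.rmst - z * self.se, self.rmst + z * self.se])


def rmst(time, event, tau: float):
    """RMST = area under the KM curve on [0, tau], with large-sample SE.

    Returns ``(rmst, se)``.  The integral is the exact step-function area;
    the variance is the standard sum over event times of the squared
    remaining area weighted by the Greenwood increments.
    """
    time, event = _check_surv(time, event)
    mx = time.max()
    if mx < tau and np.any((time == mx) & (event == 0)):
        # follow-up exhausted before tau with subjects still at risk
        raise DataError(
            f"max follow-up {mx:g} < tau {tau:g} with censored subjects at risk"
        )
    km = km_estimate(time, event) if event.sum() else None
    if km is None:
        return float(tau), 0.0
    ts = km.times[km.times <= tau]
    ss = km.surv[: ts.size]
    # step areas: S is 1 on [0, t1), surv[i] on [t_i, t_{i+1})
    grid = np.concatenate([[0.0], ts, [tau]])
    vals = np.concatenate([[1.0], ss])
    area = float(np.sum(vals * np.diff(grid)))
    # variance (Klein & Moeschberger / survRM2 form)
    var = 0.0
    for i in range(ts.size):
        n_i = km.n_risk[i]
        d_i = km.n_event[i]
        if n_i - d_i <= 0:
            continue
        # area under S from t_i to tau
        g2 = np.concatenate([[ts[i]], ts[i + 1:], [tau]])
        v2 = ss[i:]
        a_i = float(np.sum(v2 * np.diff(g2)))
        var += a_i**2 * d_i / (n_i * (n_i - d_i))
    return area, float(np.sqrt(var))


def rmst_compare(time, event, group, tau: float = DFS_HORIZON_MONTHS) -> RmstResult:
    """Compare the RMST at ``tau`` between two groups (z-test on difference)."""
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    levels = sorted(pd.unique(group))
    if len(levels) != 2:
        raise DataError("rmst_compare expects exactly two groups")
    ests, ses = [], []
    eff_tau = tau
    for g in levels:
        m = group == g
        mx = time[m].max()
        if mx < eff_tau:
            eff_tau = mx
    if eff_tau < tau:
        import warnings

        warnings.warn(
            f"follow-up ends before tau={tau:g}; truncating to {eff_tau:g}",
            stacklevel=2,
        )
    for g in levels:
        m = group == g
        a, s = rmst(time[m], event[m], eff_tau)
        ests.append(a)
        ses.append(s)
    ests = np.asarray(ests)
    ses = np.asarray(ses)
    diff = float(ests[0] - ests[1])
    dse = float(np.sqrt(ses[0] ** 2 + ses[1] ** 2))
    p = float(2 * stats.norm.sf(abs(diff) / dse)) if dse > 0 else 1.0
    return RmstResult(tau=eff_tau, groups=levels, rmst=ests, se=ses,
                      difference=diff, diff_se=dse, p=p)


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

@dataclass
class TdAucResult:
    t_eval: float
    auc: float
    estimator: str
    n_cases: int
    n_controls: int


def _censoring_km(time, event):
    """KM of the censoring distribution G(t) (events treated as censorings)."""
    return km_estimate(time, 1 - event)


def td_auc(score, time, event, t_eval: float,
           estimator: str = "cumulative_dynamic") -> TdAucResult:
    """Time-dependent AUC of a risk score (higher score = higher risk).

    ``cumulative_dynamic``: cases are subjects with an event by ``t_eval``,
    controls those event-free beyond it; case/control pairs are weighted by
    inverse probability of censoring (IPCW).  With no censoring before
    ``t_eval`` this equals the empirical ROC AUC.

    ``incident_dynamic``: risk-set estimator; at each event time ``t <=
    t_eval`` the incident case's score is ranked within the risk set, and
    the per-time AUCs are averaged with weights ``d_k * S(t_k)``.
    """
    score = np.asarray(score, dtype=float)
    time, event = _check_surv(time, event)
    if score.shape != time.shape:
        raise DataError("score must align with time")
    cases = (time <= t_eval) & (event == 1)
    controls = time > t_eval
    if cases.sum() == 0:
        raise DataError(f"no events by t_eval={t_eval:g}")
    if controls.sum() == 0:
        raise DataError(f"no controls beyond t_eval={t_eval:g}")

    if estimator == "cumulative_dynamic":
        G = _censoring_km(time, event)

        def gfun(t):
            # left-continuous censoring survival just before t
            t = np.atleast_1d(t)
            if G.times.size == 0:        # no censoring at all
                return np.ones(t.shape)
            idx = np.searchsorted(G.times, t, side="left") - 1
            return np.where(idx >= 0, G.surv[np.maximum(idx, 0)], 1.0)

        w_case = 1.0 / np.maximum(gfun(time[cases]), 1e-12)
        w_ctrl = np.full(controls.sum(), 1.0 / max(float(gfun(np.array([t_eval]))[0]), 1e-12))
        sc = score[cases]
        st = score[controls]
        # weighted probability of concordance, ties count half
        gt = (sc[:, None] > st[None, :]).astype(float)
        gt += 0.5 * (sc[:, None] == st[None, :])
        wmat = np.outer(w_case, w_ctrl)
        auc = float((gt * wmat).sum() / wmat.sum())
        n_cases, n_controls = int(cases.sum()), int(controls.sum())
    elif estimator == "incident_dynamic":
        km = km_estimate(time, event)
        ev_times = km.times[km.times <= t_eval]
        aucs, weights = [], []
        for i, u in enumerate(ev_times):
            riskset = time >= u
            case_m = (time == u) & (event == 1)
            ctrl_m = riskset & ~case_m
            if ctrl_m.sum() == 0:
                continue
            sc = score[case_m]
            st = score[ctrl_m]
            conc = (sc[:, None] > st[None, :]).mean() + 0.5 * (
                sc[:, None] == st[None, :]
            ).mean()
            surv_minus = km.surv[i - 1] if i > 0 else 1.0
            aucs.append(conc)
            weights.append(km.n_event[i] * surv_minus)
        if not aucs:
            raise DataError("no usable event times for incident/dynamic AUC")
        auc = float(np.average(aucs, weights=weights))
        n_cases = int(((time <= t_eval) & (event == 1)).sum())
        n_controls = int(controls.sum())
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return TdAucResult(t_eval=float(t_eval), auc=auc, estimator=estimator,
                       n_cases=n_cases, n_controls=n_controls)


def td_auc_auto(score, time, event, t_eval: float, ph_p: float,
                alpha: float = 0.05) -> TdAucResult:
    """Dispatch rule: PH verified (p >= alpha) -> cumulative/dynamic,
    otherwise incident/dynamic."""
    est = "cumulative_dynamic" if ph_p >= alpha else "incident_dynamic"
    return td_auc(score, time, event, t_eval, estimator=est)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def lrt_nested(fit_reduced: CoxFit, fit_full: CoxFit):
    """Likelihood-ratio test between nested Cox models.

    Returns ``(chi2, df, p)``.  Nesting is checked on term names and sample
    size; the reduced model's terms must be a subset of the full model's.
    """
    if fit_reduced.n != fit_full.n or fit_reduced.n_events != fit_full.n_events:
        raise DataError("models fitted on different data")
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise DataError("models are not nested (term sets)")
    df = len(fit_full.terms) - len(fit_reduced.terms)
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def bootstrap_auc_compare(scores: dict, time, event, t_eval: float,
                          B: int = 1000, seed: int = 0,
                          estimator: str = "cumulative_dynamic"):
    """Bootstrap comparison of model AUCs.

    ``scores`` maps model name -> risk score vector over the same patients.
    Patients are resampled with replacement B times; the time-dependent AUC
    of each model is computed on each resample.  Returns
    ``(pd.DataFrame of AUC distributions (B x models),
    pd.DataFrame of pairwise Wilcoxon rank-sum p-values)``.
    """
    if B < 2:
        raise DataError("B must be >= 2")
    if len(scores) < 2:
        raise DataError("need at least two models to compare")
    time, event = _check_surv(time, event)
    names = list(scores)
    mat = {k: np.asarray(v, dtype=float) for k, v in scores.items()}
    n = time.size
    rng = np.random.default_rng(seed)
    out = np.full((B, len(names)), np.nan)
    b = 0
    attempts = 0
    while b < B and attempts < 20 * B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            for j, k in enumerate(names):
                out[b, j] = td_auc(mat[k][idx], time[idx], event[idx],
                                   t_eval, estimator=estimator).auc
        except DataError:
            continue
        b += 1
    if b < B:
        raise DataError("too many degenerate bootstrap resamples")
    dist = pd.DataFrame(out, columns=names)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                        columns=names)
    for i, a in enumerate(names):
        for j, c in enumerate(names):
            if i < j:
                p = stats.ranksums(dist[a], dist[c]).pvalue
                pmat.loc[a, c] = pmat.loc[c, a] = p
    return dist, pmat


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DataError("pvals must be 1-d")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# stratification rules
# ---------------------------------------------------------------------------

_T_CODES = {"T1", "T2", "T3", "T4"}
_N_CODES = {"N1", "N2"}


def classify_risk_stage(t_stage, n_stage):
    """Stage-III risk stage: High iff T4 and/or N2; Low otherwise.

    Accepts scalars or aligned sequences of codes 'T1'..'T4' and 'N1'/'N2'.
    """
    scalar = np.isscalar(t_stage)
    t = np.atleast_1d(np.asarray(t_stage, dtype=object))
    n = np.atleast_1d(np.asarray(n_stage, dtype=object))
    if t.shape != n.shape:
        raise DataError("t_stage and n_stage must align")
    bad_t = sorted({str(v) for v in t} - _T_CODES)
    bad_n = sorted({str(v) for v in n} - _N_CODES)
    if bad_t or bad_n:
        raise DataError(f"unknown stage codes: T={bad_t} N={bad_n}")
    out = np.where((t == "T4") | (n == "N2"), "High", "Low")
    return out.item() if scalar else out


def _check_lh(x, what):
    bad = sorted({str(v) for v in np.atleast_1d(x) if not pd.isna(v)}
                 - {"Low", "High"})
    if bad:
        raise DataError(f"{what} must be Low/High, got {bad}")


def combine_clinical_cd3ml(clinical, cd3ml):
    """3-modality combined stratum.

    High = clinical High & score High; Low = clinical Low & score Low;
    Intermediate = the two discordant cells.  Missing inputs propagate.
    """
    scalar = np.isscalar(clinical)
    c = np.atleast_1d(np.asarray(clinical, dtype=object))
    s = np.atleast_1d(np.asarray(cd3ml, dtype=object))
    _check_lh(c, "clinical")
    _check_lh(s, "cd3ml")
    out = np.empty(c.shape, dtype=object)
    for i in range(c.size):
        if pd.isna(c.flat[i]) or pd.isna(s.flat[i]):
            out.flat[i] = np.nan
        elif c.flat[i] == "High" and s.flat[i] == "High":
            out.flat[i] = "High"
        elif c.flat[i] == "Low" and s.flat[i] == "Low":
            out.flat[i] = "Low"
        else:
            out.flat[i] = "Intermediate"
    return out.item() if scalar else out


def combine_n_cd3ml(n_stage, cd3ml):
    """4-modality stratum: cross of N status (N1/N2) with score status."""
    scalar = np.isscalar(n_stage)
    n = np.atleast_1d(np.asarray(n_stage, dtype=object))
    s = np.atleast_1d(np.asarray(cd3ml, dtype=object))
    bad_n = sorted({str(v) for v in n if not pd.isna(v)} - _N_CODES)
    if bad_n:
        raise DataError(f"unknown N codes: {bad_n}")
    _check_lh(s, "cd3ml")
    out = np.empty(n.shape, dtype=object)
    for i in range(n.size):
        if pd.isna(n.flat[i]) or pd.isna(s.flat[i]):
            out.flat[i] = np.nan
        else:
            out.flat[i] = f"{n.flat[i]}/CD3ML_{s.flat[i]}"
    return out.item() if scalar else out
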