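"""Machine-learning tumour score from tile features.

The score is built in two stages on a training cohort: (1) an L1-penalised
Cox model (coordinate descent on the Breslow partial likelihood, lambda path
with warm starts, k-fold cross-validated partial likelihood for the lambda
choice) selects a sparse subset of the 124 per-slide mean tile features;
(2) an unpenalised Cox model refitted on the selected features provides the
linear predictor, centred on the training mean.  Per cohort, the continuous
score is dichotomised at the cut-point maximising the standardized
two-sample log-rank statistic over the admissible quantile band
(maximally selected rank statistic).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstats
from .features import FEATURE_NAMES, FEATURE_REGISTRY_VERSION

__all__ = [
    "SlideFeatureProfile",
    "LassoCoxFit",
    "ScoreCutoff",
    "slide_mean_features",
    "fit_lasso_cox",
    "cd3ml_score",
    "maxstat_cutoff",
    "dichotomise_cutoff",
]


@dataclass
class SlideFeatureProfile:
    """Mean tile-feature vector of one slide (tumour tiles in TC or IM)."""

    slide_id: str
    values: np.ndarray | None      # length 124, or None when unanalysable
    n_tiles_used: int

    @property
    def valid(self) -> bool:
        return self.values is not None and self.n_tiles_used >= 1


def slide_mean_features(tile_features, label_map, regions,
                        slide_id: str = "") -> SlideFeatureProfile:
    """Mean of the feature vectors over tumour-class tiles in TC or IM.

    A tile qualifies when its class is ``tumour`` and its box centre falls
    inside the tumour core or the invasive margin.  With zero qualifying
    tiles the profile is missing (``values is None``).
    """
    t = tile_features.table.merge(
        label_map.table[["row", "col", "label"]], on=["row", "col"]
    )
    s = tile_features.tile_size_px
    mask = regions.tc_mask | regions.im_mask
    h, w = mask.shape
    keep = []
    for _, rowd in t.iterrows():
        if rowd["label"] != "tumour":
            keep.append(False)
            continue
        cx = int((rowd["col"] + 0.5) * s)
        cy = int((rowd["row"] + 0.5) * s)
        keep.append(bool(0 <= cy < h and 0 <= cx < w and mask[cy, cx]))
    sel = t[np.asarray(keep, dtype=bool)] if len(t) else t
    if len(sel) == 0:
        return SlideFeatureProfile(slide_id=slide_id, values=None, n_tiles_used=0)
    vec = sel[list(FEATURE_NAMES)].to_numpy(dtype=float).mean(axis=0)
    return SlideFeatureProfile(slide_id=slide_id, values=vec,
                               n_tiles_used=int(len(sel)))


# ---------------------------------------------------------------------------
# L1-penalised Cox (coordinate descent, Breslow ties)
# ---------------------------------------------------------------------------

def _breslow_parts(time, event):
    """Sorted-order risk-set bookkeeping reused across evaluations."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = time[order] * 0 + event[order]
    ut, first = np.unique(t[e == 1], return_index=False), None
    return order, t, event[order]


def _breslow_loglik_grad(eta, t_sorted, e_sorted):
    """Breslow partial loglik, d l / d eta and diagonal Hessian bound.

    Inputs are already sorted by ascending time.
    """
    n = eta.size
    w = np.exp(eta - eta.max())
    # suffix sums of w give S0 at each position's entry time
    suffix = np.cumsum(w[::-1])[::-1]
    ev_idx = np.nonzero(e_sorted == 1)[0]
    t_ev = t_sorted[ev_idx]
    ut, counts = np.unique(t_ev, return_counts=True)
    # S0 at each unique event time = suffix sum from the first index with t >= ut
    pos = np.searchsorted(t_sorted, ut, side="left")
    S0 = suffix[pos]
    logw_shift = eta.max()
    ll = float(eta[ev_idx].sum() - (counts * (np.log(S0) + logw_shift)).sum())
    # cumulative hazard increments
    inc1 = counts / S0
    inc2 = counts / S0**2
    c1 = np.concatenate([[0.0], np.cumsum(inc1)])
    c2 = np.concatenate([[0.0], np.cumsum(inc2)])
    # for subject i (time t_i): sum over event times <= t_i
    k = np.searchsorted(ut, t_sorted, side="right")
    A = c1[k]
    B = c2[k]
    grad = e_sorted - w * A
    hess = np.maximum(w * A - w**2 * B, 0.0)
    return ll, grad, hess


def _cd_gaussian(Xs, z, w2, beta, lam, tol=1e-7, max_iter=1000):
    """Coordinate descent for the weighted-LS lasso (no intercept).

    Active-set strategy: sweep the full coordinate set once, then iterate
    over the nonzero set until convergence; a final full sweep checks the
    KKT conditions and re-enters violating coordinates.
    """
    n, p = Xs.shape
    wx2 = (w2[:, None] * Xs**2).sum(axis=0) / n
    r = z - Xs @ beta

    def sweep(idx):
        dmax = 0.0
        for j in idx:
            if wx2[j] <= 0:
                continue
            bj = beta[j]
            rho = (w2 * Xs[:, j]) @ r / n + wx2[j] * bj
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / wx2[j]
            if new != bj:
                r[:] -= Xs[:, j] * (new - bj)
                dmax = max(dmax, abs(new - bj))
                beta[j] = new
        return dmax

    active = set(np.nonzero(beta)[0].tolist())
    it = 0
    while it < max_iter:
        # converge on the current active set
        while it < max_iter:
            it += 1
            if sweep(sorted(active)) < tol:
                break
        # KKT screen over all coordinates (one matmul)
        g = Xs.T @ (w2 * r) / n
        viol = np.nonzero((np.abs(g) > lam * (1 + 1e-9)) & (beta == 0))[0]
        viol = [j for j in viol if j not in active and wx2[j] > 0]
        if not viol:
            break
        active.update(viol)
    return beta


def _lasso_path(Xs, time, event, lambdas, tol=1e-5, max_outer=30):
    """Warm-started lambda path on standardized X; returns (L, p) betas."""
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    Xo = Xs[order]
    n, p = Xo.shape
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for li, lam in enumerate(lambdas):
        for _ in range(max_outer):
            eta = Xo @ beta
            _, grad, hess = _breslow_loglik_grad(eta, ts, es)
            w2 = np.maximum(hess, 1e-6)
            z = eta + grad / w2
            old = beta.copy()
            beta = _cd_gaussian(Xo, z, w2, beta, lam)
            if np.max(np.abs(beta - old)) < tol:
                break
        betas[li] = beta
    return betas


def _breslow_loglik(beta, Xs, time, event):
    order = np.argsort(time, kind="stable")
    eta = (Xs @ beta)[order]
    ll, _, _ = _breslow_loglik_grad(eta, time[order], event[order])
    return ll


@dataclass
class LassoCoxFit:
    """L1-penalised Cox selection plus the refitted linear predictor."""

    feature_names: list
    lambdas: np.ndarray
    path_betas: np.ndarray              # standardized scale, (L, p)
    lambda_chosen: float
    choice_rule: str
    selected: list                      # names of nonzero-coefficient features
    coef_penalised: np.ndarray          # original scale, full length
    coef_refit: np.ndarray | None       # original scale, selected features only
    refit_fallback: bool                # True when the unpenalised refit failed
    train_mean: np.ndarray              # feature means of the training cohort
    cv_scores: np.ndarray | None
    n_folds: int
    seed: int
    registry_version: str = FEATURE_REGISTRY_VERSION
    degenerate: bool = False            # empty selected set

    def to_json(self) -> str:
        return json.dumps(
            {
                "registry_version": self.registry_version,
                "lambda_chosen": float(self.lambda_chosen),
                "choice_rule": self.choice_rule,
                "selected": list(self.selected),
                "coef_refit": None if self.coef_refit is None
                else list(map(float, self.coef_refit)),
                "coef_penalised": {
                    n: float(c)
                    for n, c in zip(self.feature_names, self.coef_penalised)
                    if c != 0
                },
                "n_folds": self.n_folds,
                "seed": self.seed,
            },
            indent=2,
        )


def fit_lasso_cox(X, time, event, lambda_grid=None, n_folds: int = 5,
                  choice_rule: str = "min", seed: int = 0,
                  n_lambda: int = 30, lambda_min_ratio: float = 0.05,
                  feature_names=None) -> LassoCoxFit:
    """L1-penalised Cox regression over a lambda path with CV choice.

    ``X`` is standardised internally (coefficients are reported on the
    original scale); the penalised partial likelihood uses Breslow tie
    handling.  The cross-validated partial likelihood (Verweij-Van
    Houwelingen) selects lambda with rule ``"min"`` (maximum CV likelihood)
    or ``"1se"``.  Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j + 1:03d}" for j in range(p)]
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; selection will be unstable",
                      stacklevel=2)
    if choice_rule not in ("min", "1se"):
        raise ValueError("choice_rule must be 'min' or '1se'")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2
        )
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]

    if lambda_grid is None:
        order = np.argsort(time, kind="stable")
        _, grad0, _ = _breslow_loglik_grad(
            np.zeros(n), time[order], event[order]
        )
        g = np.abs(Xs[order].T @ grad0) / n
        lam_max = float(g.max())
        if lam_max <= 0:
            lam_max = 1e-3
        lambda_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio,
                                   n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    cv_scores = None
    se_scores = None
    if lambda_grid.size > 1:
        rng = np.random.default_rng(seed)
        folds = rng.permutation(np.arange(n) % n_folds)
        full_ll = np.zeros((n_folds, lambda_grid.size))
        for k in range(n_folds):
            tr = folds != k
            betas_k = _lasso_path(Xs[tr], time[tr], event[tr], lambda_grid)
            for li in range(lambda_grid.size):
                ll_all = _breslow_loglik(betas_k[li], Xs, time, event)
                ll_tr = _breslow_loglik(betas_k[li], Xs[tr], time[tr], event[tr])
                full_ll[k, li] = ll_all - ll_tr
        cv_scores = full_ll.sum(axis=0)
        se_scores = full_ll.std(axis=0, ddof=1) * np.sqrt(n_folds)
        best = int(np.argmax(cv_scores))
        if choice_rule == "min":
            li_chosen = best
        else:
            thresh = cv_scores[best] - se_scores[best]
            ok = np.nonzero(cv_scores >= thresh)[0]
            li_chosen = int(ok[0])          # sparsest lambda within one SE
    else:
        li_chosen = 0

    betas = _lasso_path(Xs, time, event, lambda_grid)
    beta_std = betas[li_chosen]
    coef = np.zeros(p)
    coef[keep] = beta_std[keep] / sd[keep]
    selected = [feature_names[j] for j in range(p) if coef[j] != 0]
    sel_idx = [j for j in range(p) if coef[j] != 0]

    coef_refit = None
    fallback = False
    degenerate = len(selected) == 0
    if not degenerate:
        try:
            refit = survstats.fit_cox(X[:, sel_idx], time, event)
            coef_refit = refit.beta
        except (survstats.DataError, survstats.ConvergenceError) as exc:
            warnings.warn(f"unpenalised refit failed ({exc}); "
                          "using penalised coefficients", stacklevel=2)
            coef_refit = coef[sel_idx]
            fallback = True
    return LassoCoxFit(
        feature_names=feature_names,
        lambdas=lambda_grid,
        path_betas=betas,
        lambda_chosen=float(lambda_grid[li_chosen]),
        choice_rule=choice_rule,
        selected=selected,
        coef_penalised=coef,
        coef_refit=coef_refit,
        refit_fallback=fallback,
        train_mean=mean,
        cv_scores=cv_scores,
        n_folds=n_folds,
        seed=seed,
        degenerate=degenerate,
    )


def cd3ml_score(fit: LassoCoxFit, X, use_refit: bool = True) -> np.ndarray:
    """Linear-predictor score, centred on the training-cohort mean.

    With ``use_refit`` (default) the two-stage coefficients are used;
    otherwise the penalised coefficients.  An empty selected set yields
    all-zero scores (the fit carries ``degenerate=True``).
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in fit.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing selected feature(s): {missing[:5]}")
        X = X[fit.feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.feature_names):
        raise ValueError("X not aligned with the fitted feature registry")
    if fit.degenerate:
        return np.zeros(X.shape[0])
    sel_idx = [fit.feature_names.index(s) for s in fit.selected]
    Xc = X[:, sel_idx] - fit.train_mean[sel_idx]
    beta = fit.coef_refit if (use_refit and fit.coef_refit is not None) \
        else fit.coef_penalised[sel_idx]
    return Xc @ beta


# ---------------------------------------------------------------------------
# maximally selected log-rank cut-point
# ---------------------------------------------------------------------------

@dataclass
class ScoreCutoff:
    cohort: str
    cutoff: float
    statistic: float          # standardized log-rank statistic at the cut
    minprop: float
    candidates_scanned: int = 0


def maxstat_cutoff(score, time, event, minprop: float = 0.1,
                   cohort: str = "all") -> ScoreCutoff:
    """Best survival cut-point by maximally selected log-rank statistic.

    Candidate cuts are midpoints between consecutive ordered unique scores
    whose induced low-group proportion lies in ``[minprop, 1 - minprop]``;
    the returned cut maximises the absolute standardized two-sample log-rank
    statistic, ties broken toward the cut nearest the score median.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.unique(score)
    if uniq.size < 2:
        raise ValueError("constant scores: no cut-point exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    prop = np.array([(score <= m).mean() for m in mids])
    ok = (prop > minprop) & (prop < 1 - minprop)    # strictly inside the band
    cands = mids[ok]
    if cands.size == 0:
        raise ValueError("no candidate cuts inside the minprop band")
    med = np.median(score)
    best = None
    for m in cands:
        grp = np.where(score > m, "High", "Low")
        try:
            z = survstats.logrank_z(time, event, grp)
        except survstats.DataError:
            continue
        key = (abs(z), -abs(m - med))
        if best is None or key > best[0]:
            best = (key, m, z)
    if best is None:
        raise ValueError("no candidate cut admits a log-rank statistic")
    _, cut, z = best
    return ScoreCutoff(cohort=cohort, cutoff=float(cut), statistic=float(z),
                       minprop=minprop, candidates_scanned=int(cands.size))


def dichotomise_cutoff(score, cutoff: float):
    """High iff score > cutoff (score equal to the cutoff goes Low)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    score = np.asarray(score, dtype=float)
    return np.where(score > cutoff, "High", "Low")
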