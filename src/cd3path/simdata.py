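"""Synthetic slides and survival cohorts with recorded ground truth.

Two generators back the whole test surface:

* :func:`generate_slide` draws a desk-scale H-DAB-like RGB slide: a tissue
  region on glass, simply-connected tumour blobs with a texture distinct
  from stroma, and DAB-brown discs ("CD3+ cells") placed by a homogeneous
  spatial Poisson process per region.  The image is composed in optical
  density with the same Ruifrok H-DAB basis the imaging module deconvolves
  with, so stain separation is exact up to 8-bit quantisation.

* :func:`generate_cohort` draws a proportional-hazards cohort: a feature
  matrix with a sparse linear effect on the log-hazard, a binary clinical
  risk factor whose log hazard ratio switches at a knot (piecewise
  exponential, sampled by exact inverse-CDF), random censoring, and
  administrative censoring at 60 months.

All randomness flows through ``numpy.random.default_rng`` (PCG64); the same
seed gives bit-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import HDAB_BASIS, SlideImage, compose_od

__all__ = [
    "SlideSimParams",
    "CohortSimParams",
    "GroundTruth",
    "generate_slide",
    "generate_cohort",
    "generate_linked_cohort",
    "MARGIN_UM",
]

MARGIN_UM = 300.0           # invasive-margin band width used for truth masks
MIN_SIDE_PX = 320           # >= 10 tiles of the minimum 32 px tile size


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SlideSimParams:
    """Parameters of one synthetic H-DAB slide."""

    width_px: int = 640
    height_px: int = 640
    mpp: float = 1.0                        # microns per pixel
    tumour_blob_count: int = 3
    tumour_fraction_target: float = 0.3     # of tissue area
    cd3_density_tc: float = 800.0           # cells / mm^2
    cd3_density_im: float = 800.0
    cd3_density_stroma: float = 200.0
    cell_radius_um: float = 3.0
    stain_noise_sd: float = 0.01            # OD-scale additive noise
    # optional hard-core spacing (Matern-II thinning of the Poisson draw);
    # None keeps the pure Poisson process (cells may touch and merge)
    min_cell_spacing_um: float | None = None
    seed: int = 0

    def validate(self):
        if self.width_px < MIN_SIDE_PX or self.height_px < MIN_SIDE_PX:
            raise ParameterError(
                f"slide must be at least {MIN_SIDE_PX} px per side "
                f"(10 tiles at the minimum tile size)"
            )
        if self.mpp <= 0:
            raise ParameterError("mpp must be positive")
        if self.cell_radius_um <= 0:
            raise ParameterError("cell radius must be positive")
        for name in ("cd3_density_tc", "cd3_density_im", "cd3_density_stroma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not (0 <= self.tumour_fraction_target <= 1):
            raise ParameterError("tumour_fraction_target must lie in [0,1]")


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of a synthetic survival cohort.

    Event times follow h(t) = baseline_hazard * exp(X beta + r(t)) with
    r(t) the risk-stage contribution: ``risk_beta_early`` before
    ``knot_months`` and ``risk_beta_late`` after, for high-risk patients.
    """

    n_patients: int = 200
    n_features: int = 124
    true_support: tuple = ()
    true_beta: tuple = ()
    feature_corr: float = 0.0               # equicorrelation of feature columns
    baseline_hazard: float = 0.01           # events per month
    risk_stage_prevalence: float = 0.45
    risk_beta_early: float = 0.0
    risk_beta_late: float = 0.0
    knot_months: float = 22.0
    censor_admin_months: float = 60.0
    censor_random_rate: float = 0.003       # per month
    seed: int = 0

    def validate(self):
        if self.n_patients < 2:
            raise ParameterError("need at least two patients")
        if len(self.true_support) != len(self.true_beta):
            raise ParameterError("true_support and true_beta length mismatch")
        if len(self.true_support) > self.n_features:
            raise ParameterError("support larger than feature count")
        if any(j < 0 or j >= self.n_features for j in self.true_support):
            raise ParameterError("support index out of range")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline hazard must be positive")
        if not (0 <= self.risk_stage_prevalence <= 1):
            raise ParameterError("prevalence must lie in [0,1]")
        if self.censor_random_rate < 0:
            raise ParameterError("censoring rate must be non-negative")
        if not (0 < self.knot_months):
            raise ParameterError("knot must be positive")
        if not (0 <= self.feature_corr < 1):
            raise ParameterError("feature_corr must lie in [0,1)")


@dataclass
class GroundTruth:
    """Exact truth record of a synthetic slide."""

    tumour_mask: np.ndarray                 # bool, tumour core truth
    im_mask: np.ndarray                     # bool, 300 um margin band truth
    tissue_mask: np.ndarray
    cell_centres: pd.DataFrame              # columns x_px, y_px, region
    densities: dict = field(default_factory=dict)   # region -> cells/mm^2
    areas_mm2: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

def _smooth_noise(rng, shape, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _superellipse_mask(h, w, cx, cy, rx, ry, exponent, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / rx
    v = (-dx * st + dy * ct) / ry
    return (np.abs(u) ** exponent + np.abs(v) ** exponent) <= 1.0


def _place_poisson(rng, mask, density_per_mm2, mpp, min_spacing_px=None):
    """Uniform Poisson point process on a pixel mask; returns (x, y) floats.

    With ``min_spacing_px`` the draw is thinned to a hard-core process
    (points closer than the spacing to an earlier kept point are removed).
    """
    area_mm2 = mask.sum() * mpp**2 / 1e6
    n = rng.poisson(density_per_mm2 * area_mm2)
    if n == 0 or not mask.any():
        return np.empty((0, 2))
    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, xs.size, size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    pts = np.column_stack([xs[idx] + jitter[:, 0], ys[idx] + jitter[:, 1]])
    if min_spacing_px:
        from scipy.spatial import cKDTree

        kept: list = []
        tree = None
        for p in pts:
            if tree is not None and tree.query(p, k=1)[0] < min_spacing_px:
                continue
            kept.append(p)
            tree = cKDTree(np.asarray(kept))
        pts = np.asarray(kept) if kept else np.empty((0, 2))
    return pts


def generate_slide(params: SlideSimParams, slide_id: str = "sim"):
    """Generate one synthetic H-DAB slide and its ground truth."""
    params.validate()
    h, w = params.height_px, params.width_px
    mpp = params.mpp
    rng = np.random.default_rng(params.seed)

    # tissue: the slide minus a wavy glass border (~4% inset)
    inset = max(int(0.04 * min(h, w)), 4)
    tissue = np.zeros((h, w), dtype=bool)
    tissue[inset:-inset, inset:-inset] = True
    wave = _smooth_noise(rng, (h, w), sigma=min(h, w) / 10)
    edt = ndimage.distance_transform_edt(tissue)
    tissue &= edt + wave * inset * 0.6 > 0.5 * inset

    # tumour blobs: smoothed random super-ellipses, simply connected
    tumour = np.zeros((h, w), dtype=bool)
    if params.tumour_blob_count > 0 and params.tumour_fraction_target > 0:
        target_area = params.tumour_fraction_target * tissue.sum()
        per_blob = target_area / params.tumour_blob_count
        r0 = np.sqrt(per_blob / np.pi)
        for _ in range(params.tumour_blob_count):
            cx = rng.uniform(0.25 * w, 0.75 * w)
            cy = rng.uniform(0.25 * h, 0.75 * h)
            rx = r0 * rng.uniform(0.75, 1.3)
            ry = per_blob / np.pi / rx
            ex = rng.uniform(1.6, 2.8)
            th = rng.uniform(0, np.pi)
            blob = _superellipse_mask(h, w, cx, cy, rx, ry, ex, th)
            blob = ndimage.gaussian_filter(blob.astype(float), r0 * 0.08) > 0.5
            ndimage.binary_fill_holes(blob, output=blob)
            tumour |= blob
        tumour &= tissue
        tumour = ndimage.binary_fill_holes(tumour)

    # margin band: 0 < d(., tumour) <= 300 um, within tissue
    if tumour.any():
        d = ndimage.distance_transform_edt(~tumour)
        band = (d > 0) & (d <= MARGIN_UM / mpp)
        im = band & tissue
    else:
        im = np.zeros((h, w), dtype=bool)
    stroma = tissue & ~tumour & ~im

    # haematoxylin texture: tumour has high-frequency, high-variance texture;
    # stroma is smooth.  Levels chosen so generic intensity/texture features
    # separate the classes without any engineered single feature.
    od_h = np.zeros((h, w))
    od_h[tissue] = 0.45
    tex_tum = 0.28 * _smooth_noise(rng, (h, w), sigma=1.2)
    tex_str = 0.08 * _smooth_noise(rng, (h, w), sigma=6.0)
    od_h += np.where(tumour, tex_tum + 0.15, np.where(tissue, tex_str, 0.0))
    od_h = np.clip(od_h, 0.0, 1.6)

    # CD3+ cells: Poisson process per region, brown DAB discs
    regions = {
        "TC": (tumour, params.cd3_density_tc),
        "IM": (im, params.cd3_density_im),
        "stroma": (stroma, params.cd3_density_stroma),
    }
    recs = []
    densities = {}
    areas = {}
    od_d = np.zeros((h, w))
    r_px = params.cell_radius_um / mpp
    yy, xx = np.mgrid[0:h, 0:w]
    spacing_px = (params.min_cell_spacing_um / mpp
                  if params.min_cell_spacing_um else None)
    for name, (mask, dens) in regions.items():
        pts = _place_poisson(rng, mask, dens, mpp, min_spacing_px=spacing_px)
        area_mm2 = mask.sum() * mpp**2 / 1e6
        areas[name] = area_mm2
        densities[name] = pts.shape[0] / area_mm2 if area_mm2 > 0 else np.nan
        for x, y in pts:
            recs.append((x, y, name))
            x0, x1 = max(int(x - r_px - 2), 0), min(int(x + r_px + 3), w)
            y0, y1 = max(int(y - r_px - 2), 0), min(int(y + r_px + 3), h)
            d2 = (xx[y0:y1, x0:x1] - x) ** 2 + (yy[y0:y1, x0:x1] - y) ** 2
            od_d[y0:y1, x0:x1] = np.maximum(
                od_d[y0:y1, x0:x1], 0.85 * (d2 <= r_px**2)
            )
    od_d = ndimage.gaussian_filter(od_d, 0.5)

    if params.stain_noise_sd > 0:
        od_h = np.clip(od_h + rng.normal(0, params.stain_noise_sd, (h, w)), 0, None)
        od_d = np.clip(od_d + rng.normal(0, params.stain_noise_sd, (h, w)), 0, None)

    od_rgb = od_h[..., None] * HDAB_BASIS[0] + od_d[..., None] * HDAB_BASIS[1]
    pixels = compose_od(od_rgb)
    slide = SlideImage(pixels=pixels, mpp=mpp, slide_id=slide_id)
    cells = pd.DataFrame(recs, columns=["x_px", "y_px", "region"])
    truth = GroundTruth(
        tumour_mask=tumour,
        im_mask=im,
        tissue_mask=tissue,
        cell_centres=cells,
        densities=densities,
        areas_mm2=areas,
    )
    return slide, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_event_times(rng, eta, risk_high, p: CohortSimParams):
    """Exact inverse-CDF sampling of the piecewise-exponential model."""
    n = eta.size
    e = rng.exponential(1.0, size=n)        # unit-exponential deviates
    h0 = p.baseline_hazard
    knot = p.knot_months
    rate_early = h0 * np.exp(eta + risk_high * p.risk_beta_early)
    rate_late = h0 * np.exp(eta + risk_high * p.risk_beta_late)
    h_at_knot = rate_early * knot           # cumulative hazard at the knot
    t = np.where(
        e < h_at_knot,
        e / rate_early,
        knot + (e - h_at_knot) / rate_late,
    )
    return t


def _stage_codes(rng, risk_high):
    """T/N stage codes consistent with the risk-stage rule (High = T4 or N2)."""
    n = risk_high.size
    t = np.array([f"T{k}" for k in rng.integers(1, 4, size=n)], dtype=object)
    nn = np.full(n, "N1", dtype=object)
    u = rng.random(n)
    hi = risk_high.astype(bool)
    # high-risk: T4 only / N2 only / both, roughly matching observed mixes
    t[hi & (u < 0.45)] = "T4"
    nn[hi & (u >= 0.30)] = "N2"
    return t, nn


def generate_cohort(params: CohortSimParams, cohort_label: str = "sim"):
    """Generate a proportional-hazards cohort table plus its truth record.

    Returns ``(table, truth)`` where ``table`` has columns
    ``patient_id, time_months, event, t_stage, n_stage, cohort,
    f001..f{n_features}`` and ``truth`` records the latent quantities
    (linear predictor, risk class, uncensored event times).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, p = params.n_patients, params.n_features
    Z = rng.standard_normal((n, p))
    if params.feature_corr > 0:
        f = rng.standard_normal((n, 1))
        rho = params.feature_corr
        X = np.sqrt(1 - rho) * Z + np.sqrt(rho) * f
    else:
        X = Z
    beta = np.zeros(p)
    for j, b in zip(params.true_support, params.true_beta):
        beta[j] = b
    eta = X @ beta
    risk_high = (rng.random(n) < p_risk(params)).astype(int)
    t_event = _sample_event_times(rng, eta, risk_high, params)
    if params.censor_random_rate > 0:
        t_cens = rng.exponential(1.0 / params.censor_random_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_admin = params.censor_admin_months
    t_obs = np.minimum.reduce([t_event, t_cens, np.full(n, t_admin)])
    event = (t_event <= np.minimum(t_cens, t_admin)).astype(int)
    t_stage, n_stage = _stage_codes(rng, risk_high)
    table = pd.DataFrame(
        {
            "patient_id": [f"{cohort_label}-{i:05d}" for i in range(n)],
            "time_months": t_obs,
            "event": event,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "cohort": cohort_label,
        }
    )
    feats = pd.DataFrame(X, columns=[f"f{j + 1:03d}" for j in range(p)])
    table = pd.concat([table, feats], axis=1)
    truth = {
        "beta": beta,
        "eta": eta,
        "risk_high": risk_high,
        "event_time": t_event,
        "censor_time": np.minimum(t_cens, t_admin),
    }
    return table, truth


def p_risk(params: CohortSimParams) -> float:
    return params.risk_stage_prevalence


def generate_linked_cohort(slide_params_by_risk: dict,
                           cohort_params: CohortSimParams,
                           cohort_label: str = "sim"):
    """Cohort in which a latent risk class drives both slide and hazard.

    ``slide_params_by_risk`` maps 'Low'/'High' to :class:`SlideSimParams`
    templates (their ``seed`` is re-derived per patient).  Each patient's
    latent class sets both the slide generator used for their slide and the
    risk-stage hazard contribution.  Returns ``(slides, table, truth)``
    where ``slides`` maps patient_id to ``(SlideImage, GroundTruth)``.
    """
    for k in ("Low", "High"):
        if k not in slide_params_by_risk:
            raise ParameterError(f"missing slide parameters for stratum {k!r}")
    if cohort_params.n_patients == 0:
        return {}, pd.DataFrame(), {}
    cohort_params.validate()
    # the linked design carries no external feature matrix: image features
    # are measured downstream, so the cohort's own f-columns are dropped
    cp = replace(cohort_params, n_features=1, true_support=(), true_beta=())
    table, truth = generate_cohort(cp, cohort_label=cohort_label)
    table = table.drop(columns=["f001"])
    ss = np.random.SeedSequence(cohort_params.seed)
    child_seeds = ss.spawn(cohort_params.n_patients)
    slides = {}
    latent = np.where(truth["risk_high"] == 1, "High", "Low")
    for i, pid in enumerate(table["patient_id"]):
        base = slide_params_by_risk[latent[i]]
        sp = replace(base, seed=int(child_seeds[i].generate_state(1)[0] % (2**31)))
        slides[pid] = generate_slide(sp, slide_id=pid)
    table = table.copy()
    table["latent_risk"] = latent
    return slides, table, truth
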