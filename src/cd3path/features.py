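"""The frozen 124-feature tile descriptor bank.

The bank characterises a tile the way interactive pathology platforms do:
intensity statistics, grey-level co-occurrence (Haralick) texture, gradient
and edge content, local binary patterns, stain-blob morphometry, spatial
layout, colour, entropy and structural summaries.  It is computed on three
channels — grey luminance, haematoxylin OD and DAB OD — and is pure,
deterministic, and finite for any 8-bit RGB input (degenerate statistics on
constant tiles are mapped to 0).

The registry (names and order) is frozen and versioned; downstream models
record the version so a fitted score can refuse mismatched features.

Groups (124 total):
  intensity: mean, sd, skew, kurtosis, min, max, deciles q10..q90   11 x 3 = 33
  Haralick (13 stats, GLCM averaged over 4 offsets)                 13 x 3 = 39
  gradient magnitude mean/sd + edge density                          3 x 3 =  9
  uniform LBP (P=8, R=1) 10-bin histogram on grey                           10
  blob morphometry after Otsu on H and DAB OD                        6 x 2 = 12
  quadrant grey means and sds (2x2 layout)                                    8
  tissue fraction; saturation mean/sd; circular hue mean/sd                   5
  Shannon entropy per channel                                                 3
  edge fractal (box-count slope); granulometry at 4 scales                    5
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage.filters import threshold_otsu

FEATURE_REGISTRY_VERSION = "cd3path-124/1"

_CHANNELS = ("grey", "hod", "dab")
_HARALICK = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_avg",
    "sum_var",
    "sum_entropy",
    "entropy",
    "diff_var",
    "diff_entropy",
    "imc1",
    "imc2",
)
_GRAN_SIZES = (3, 5, 9, 17)     # square structuring-element side, px


def _registry():
    names = []
    for c in _CHANNELS:
        names += [f"{c}_{s}" for s in
                  ("mean", "sd", "skew", "kurt", "min", "max",
                   "q10", "q30", "q50", "q70", "q90")]
    for c in _CHANNELS:
        names += [f"{c}_glcm_{s}" for s in _HARALICK]
    for c in _CHANNELS:
        names += [f"{c}_grad_mean", f"{c}_grad_sd", f"{c}_edge_density"]
    names += [f"grey_lbp_{i:02d}" for i in range(10)]
    for c in ("hod", "dab"):
        names += [f"{c}_blob_{s}" for s in
                  ("count", "area_mean_um2", "area_sd_um2",
                   "ecc_mean", "extent_mean", "density_mm2")]
    for q in range(4):
        names += [f"grey_quad{q}_mean"]
    for q in range(4):
        names += [f"grey_quad{q}_sd"]
    names += ["tissue_fraction", "sat_mean", "sat_sd", "hue_cmean", "hue_csd"]
    names += [f"{c}_entropy" for c in _CHANNELS]
    names += ["edge_fractal_dim"] + [f"grey_gran_s{s}" for s in _GRAN_SIZES]
    return tuple(names)


FEATURE_NAMES = _registry()
assert len(FEATURE_NAMES) == 124
assert len(set(FEATURE_NAMES)) == 124

_EDGE_GRAD_THRESHOLD = 0.10     # on [0, 1]-scaled channels
_GLCM_LEVELS = 32
_EPS = 1e-12


def _finite(x, default=0.0):
    x = float(x)
    return x if np.isfinite(x) else default


_DECILES = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


def _intensity_stats(ch):
    flat = ch.ravel()
    m = flat.mean()
    d = flat - m
    d2 = d * d
    v = d2.mean()
    sd = np.sqrt(v)
    if sd < _EPS:
        skew = kurt = 0.0
    else:
        skew = _finite((d2 * d).mean() / (sd * v))
        kurt = _finite((d2 * d2).mean() / (v * v) - 3.0)
    s = np.sort(flat)
    pos = _DECILES * (s.size - 1)
    lo = pos.astype(int)
    frac = pos - lo
    q = s[lo] * (1 - frac) + s[np.minimum(lo + 1, s.size - 1)] * frac
    return [m, sd, skew, kurt, s[0], s[-1], *q]


def _quantize(ch, levels=_GLCM_LEVELS):
    lo, hi = ch.min(), ch.max()
    if hi - lo < _EPS:
        return np.zeros(ch.shape, dtype=np.uint8)
    q = ((ch - lo) / (hi - lo) * (levels - 1)).astype(np.uint8)
    return q


def _haralick(ch):
    """13 Haralick statistics from a symmetric GLCM averaged over 4 offsets."""
    q = _quantize(ch)
    glcm = skfeature.graycomatrix(
        q, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=_GLCM_LEVELS, symmetric=True, normed=False,
    ).astype(float)
    P = glcm[:, :, 0, :].mean(axis=2)
    tot = P.sum()
    if tot <= 0:
        return [0.0] * 13
    P /= tot
    L = P.shape[0]
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(i @ px)
    sigma2 = float(((i - mu) ** 2) @ px)
    sigma = np.sqrt(sigma2)
    asm = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sigma < _EPS:
        corr = 0.0
    else:
        corr = float(((ii - mu) * (jj - mu) * P).sum() / sigma2)
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    # sum / difference distributions
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (ii + jj).ravel(), P.ravel())
    k = np.arange(2 * L - 1)
    sum_avg = float(k @ psum)
    sum_var = float(((k - sum_avg) ** 2) @ psum)
    sum_ent = float(-(psum[psum > 0] * np.log(psum[psum > 0])).sum())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), P.ravel())
    kd = np.arange(L)
    dmu = float(kd @ pdiff)
    diff_var = float(((kd - dmu) ** 2) @ pdiff)
    diff_ent = float(-(pdiff[pdiff > 0] * np.log(pdiff[pdiff > 0])).sum())
    ent = float(-(P[P > 0] * np.log(P[P > 0])).sum())
    # information measures of correlation
    pxy = np.outer(px, px)           # symmetric GLCM: py = px
    m = pxy > 0
    hxy1 = float(-(P[m] * np.log(pxy[m])).sum())
    hxy2 = float(-(pxy[m] * np.log(pxy[m])).sum())
    hx = float(-(px[px > 0] * np.log(px[px > 0])).sum())
    denom = max(hx, _EPS)
    imc1 = _finite((ent - hxy1) / denom) if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))
    return [asm, contrast, corr, sigma2, idm, sum_avg, sum_var, sum_ent,
            ent, diff_var, diff_ent, imc1, imc2]


def _gradient_stats(ch):
    gy = ndimage.sobel(ch, axis=0, mode="reflect") / 8.0
    gx = ndimage.sobel(ch, axis=1, mode="reflect") / 8.0
    mag = np.hypot(gx, gy)
    return [mag.mean(), mag.std(), float((mag > _EDGE_GRAD_THRESHOLD).mean())]


def _lbp_hist(grey):
    lbp = skfeature.local_binary_pattern(
        (grey * 255).astype(np.uint8), P=8, R=1, method="uniform"
    )
    hist = np.bincount(lbp.astype(int).ravel(), minlength=10)[:10]
    return list(hist / max(hist.sum(), 1))


def _blob_stats(od, mpp):
    """Otsu-threshold blob morphometry on one OD channel.

    Per-region moments are accumulated with bincount (one pass) rather than
    per-region property objects; compactness is the extent (area over
    bounding-box area).
    """
    span = od.max() - od.min()
    area_mm2 = od.size * mpp**2 / 1e6
    if span < 0.05:                  # effectively stain-free tile
        return [0.0] * 6
    thr = threshold_otsu(od)
    binim = od > thr
    if not binim.any() or binim.all():
        return [0.0] * 6
    lab, n = ndimage.label(binim, structure=np.ones((3, 3), dtype=int))
    flat = lab.ravel()
    yy, xx = np.mgrid[0:od.shape[0], 0:od.shape[1]]
    x = xx.ravel().astype(float)
    y = yy.ravel().astype(float)
    areas = np.bincount(flat, minlength=n + 1)[1:].astype(float)
    sx = np.bincount(flat, weights=x, minlength=n + 1)[1:]
    sy = np.bincount(flat, weights=y, minlength=n + 1)[1:]
    sxx = np.bincount(flat, weights=x * x, minlength=n + 1)[1:]
    syy = np.bincount(flat, weights=y * y, minlength=n + 1)[1:]
    sxy = np.bincount(flat, weights=x * y, minlength=n + 1)[1:]
    mx, my = sx / areas, sy / areas
    # central second moments (+1/12 pixel-grid correction keeps 1-px blobs sane)
    cxx = sxx / areas - mx**2 + 1 / 12
    cyy = syy / areas - my**2 + 1 / 12
    cxy = sxy / areas - mx * my
    tr = cxx + cyy
    det = cxx * cyy - cxy**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
    l1 = tr / 2 + disc
    l2 = np.maximum(tr / 2 - disc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.sqrt(np.clip(1.0 - l2 / np.where(l1 > 0, l1, 1.0), 0.0, 1.0))
    slices = ndimage.find_objects(lab)
    bbox = np.array([(s[0].stop - s[0].start) * (s[1].stop - s[1].start)
                     for s in slices], dtype=float)
    extent = areas / bbox
    areas_um2 = areas * mpp**2
    count = float(n)
    return [
        count,
        float(areas_um2.mean()),
        float(areas_um2.std()),
        _finite(ecc.mean()),
        _finite(extent.mean()),
        count / area_mm2,
    ]


def _quadrant_stats(grey):
    h, w = grey.shape
    h2, w2 = h // 2, w // 2
    quads = [grey[:h2, :w2], grey[:h2, w2:], grey[h2:, :w2], grey[h2:, w2:]]
    return [q.mean() for q in quads] + [q.std() for q in quads]


def _colour_stats(rgb, hod, dab):
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, _EPS), 0.0)
    tissue_fraction = float(((hod + dab) > 0.15).mean())
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    hue = np.arctan2(np.sqrt(3.0) * (g - b), 2.0 * r - g - b)
    c, s = np.cos(hue).mean(), np.sin(hue).mean()
    cmean = float(np.arctan2(s, c))
    R = np.hypot(c, s)
    csd = float(np.sqrt(max(0.0, -2.0 * np.log(max(R, _EPS)))))
    return [tissue_fraction, float(sat.mean()), float(sat.std()), cmean,
            min(csd, 10.0)]


def _entropy(ch):
    hist, _ = np.histogram(ch, bins=64, range=(ch.min(), ch.max() + _EPS))
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _fractal_dim(grey):
    """Box-count slope of the Canny edge set (0 when no edges)."""
    edges = skfeature.canny(grey, sigma=1.0)
    if not edges.any():
        return 0.0
    n = min(edges.shape)
    sizes = [s for s in (2, 4, 8, 16) if s < n]
    counts = []
    for s in sizes:
        h = edges.shape[0] // s * s
        w = edges.shape[1] // s * s
        view = edges[:h, :w].reshape(h // s, s, w // s, s)
        counts.append(view.any(axis=(1, 3)).sum())
    if len(sizes) < 2 or min(counts) == 0:
        return 0.0
    slope, _ = np.polyfit(np.log(sizes), np.log(counts), 1)
    return _finite(-slope)


def _granulometry(grey):
    """Fraction of total intensity removed by grey openings at 4 scales."""
    total = grey.sum()
    if total < _EPS:
        return [0.0] * len(_GRAN_SIZES)
    out = []
    for s in _GRAN_SIZES:
        opened = ndimage.grey_opening(grey, size=(s, s))
        out.append(float(1.0 - opened.sum() / total))
    return out


def extract_tile_features(tile_rgb: np.ndarray, stains, mpp: float) -> np.ndarray:
    """Compute the 124-feature descriptor of one RGB tile.

    ``stains`` is the tile's :class:`~cd3path.imaging.StainPair`; ``mpp``
    converts pixel areas to physical units for the morphometric features.
    """
    tile = np.asarray(tile_rgb)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("tile must be (H, W, 3)")
    rgb = tile.astype(float) / 255.0
    grey = rgb @ np.array([0.2126, 0.7152, 0.0722])
    hod = np.asarray(stains.h_od, dtype=float)
    dab = np.asarray(stains.dab_od, dtype=float)
    if hod.shape != grey.shape:
        raise ValueError("stain images do not match the tile size")
    chans = {"grey": grey, "hod": hod, "dab": dab}

    vals: list[float] = []
    for c in _CHANNELS:
        vals += _intensity_stats(chans[c])
    for c in _CHANNELS:
        vals += _haralick(chans[c])
    for c in _CHANNELS:
        vals += _gradient_stats(chans[c])
    vals += _lbp_hist(grey)
    vals += _blob_stats(hod, mpp)
    vals += _blob_stats(dab, mpp)
    vals += _quadrant_stats(grey)
    vals += _colour_stats(rgb, hod, dab)
    for c in _CHANNELS:
        vals += [_entropy(chans[c])]
    vals += [_fractal_dim(grey)]
    vals += _granulometry(grey)
    out = np.asarray(vals, dtype=float)
    assert out.size == 124
    out[~np.isfinite(out)] = 0.0
    return out
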