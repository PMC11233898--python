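"""CD3+ cell detection, regional densities and median dichotomisation.

Detection operates on the DAB optical-density channel: Gaussian smoothing,
fixed OD threshold, small-object removal, and splitting of touching cells at
local maxima of the distance transform (watershed), yielding one centre per
cell.  Densities are counts per region area in mm^2.  Per-cohort scores are
dichotomised at the cohort median (ties go Low), and the combined CD3 status
is High only when both the tumour-core and invasive-margin densities are
High.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .imaging import SlideImage, deconvolve_hdab

__all__ = [
    "CellDetections",
    "DensityRecord",
    "detect_cd3_cells",
    "compute_density",
    "dichotomise_median",
    "combine_cd3",
    "quantify_slide",
]

# detection defaults at lymphocyte scale; all configurable and logged in the
# detection record
DEFAULT_SIGMA_UM = 1.0
DEFAULT_DAB_OD_THRESHOLD = 0.15
DEFAULT_MIN_AREA_UM2 = 8.0
DEFAULT_MIN_SEPARATION_UM = 4.0


@dataclass
class CellDetections:
    """Detected cell centres restricted to a region mask."""

    centres: pd.DataFrame             # columns x_px, y_px, region
    params: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.centres)


@dataclass
class DensityRecord:
    slide_id: str
    cd3_tc: float
    cd3_im: float
    tc_area_mm2: float
    im_area_mm2: float


def detect_cd3_cells(slide: SlideImage, region_mask: np.ndarray,
                     region_label: str = "TC",
                     dab_od_threshold: float = DEFAULT_DAB_OD_THRESHOLD,
                     min_area_um2: float = DEFAULT_MIN_AREA_UM2,
                     min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
                     sigma_um: float = DEFAULT_SIGMA_UM) -> CellDetections:
    """Detect DAB-positive cells whose centres fall inside ``region_mask``."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != slide.shape:
        raise ValueError("region mask does not match the slide")
    if not region_mask.any():
        raise ValueError("empty region mask")
    mpp = slide.mpp
    stains = deconvolve_hdab(slide.pixels)
    dab = ndimage.gaussian_filter(stains.dab_od, sigma_um / mpp)
    binim = dab > dab_od_threshold
    min_px = max(int(round(min_area_um2 / mpp**2)), 1)
    lab, n = ndimage.label(binim)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        small = np.where(sizes < min_px)[0] + 1
        if small.size:
            binim &= ~np.isin(lab, small)
    centres = []
    if binim.any():
        dist = ndimage.distance_transform_edt(binim)
        sep_px = max(int(round(min_separation_um / mpp)), 1)
        peaks = peak_local_max(dist, min_distance=sep_px, labels=binim,
                               exclude_border=False)
        if peaks.size == 0:
            markers = None
        else:
            markers = np.zeros_like(binim, dtype=int)
            markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
        if markers is not None:
            cells = watershed(-dist, markers=markers, mask=binim)
            coms = ndimage.center_of_mass(binim, cells,
                                          index=np.arange(1, peaks.shape[0] + 1))
            for cy, cx in coms:
                if np.isfinite(cx) and region_mask[int(round(cy)), int(round(cx))]:
                    centres.append((cx, cy, region_label))
    df = pd.DataFrame(centres, columns=["x_px", "y_px", "region"])
    return CellDetections(
        centres=df,
        params={
            "dab_od_threshold": dab_od_threshold,
            "min_area_um2": min_area_um2,
            "min_separation_um": min_separation_um,
            "sigma_um": sigma_um,
            "region": region_label,
        },
    )


def compute_density(detections: CellDetections | int,
                    region_area_mm2: float) -> float:
    """Cells per mm^2: count / area."""
    if region_area_mm2 <= 0:
        raise ValueError("region area must be positive")
    count = detections if isinstance(detections, (int, np.integer)) \
        else detections.count
    return float(count) / float(region_area_mm2)


def quantify_slide(slide: SlideImage, regions, **detect_kwargs) -> DensityRecord:
    """TC and IM CD3+ densities of one slide (NaN when a region is empty)."""
    out = {}
    for label, mask, area in (
        ("TC", regions.tc_mask, regions.tc_area_mm2),
        ("IM", regions.im_mask, regions.im_area_mm2),
    ):
        if area <= 0:
            out[label] = np.nan
            continue
        det = detect_cd3_cells(slide, mask, region_label=label, **detect_kwargs)
        out[label] = compute_density(det, area)
    return DensityRecord(
        slide_id=slide.slide_id,
        cd3_tc=out["TC"],
        cd3_im=out["IM"],
        tc_area_mm2=regions.tc_area_mm2,
        im_area_mm2=regions.im_area_mm2,
    )


def dichotomise_median(values, cohort=None):
    """Per-cohort median split: High iff value > cohort median (ties Low).

    ``values`` is a numeric vector; ``cohort`` an aligned grouping vector
    (a single cohort when omitted).  Missing values get missing labels and
    are excluded from the cutoff.  Returns ``(labels, cutoffs)`` with
    ``cutoffs`` a dict cohort -> median.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    if cohort is None:
        cohort = np.full(v.size, "all", dtype=object)
    cohort = pd.Series(np.asarray(cohort, dtype=object))
    labels = pd.Series(np.full(v.size, np.nan, dtype=object))
    cutoffs = {}
    for name, idx in cohort.groupby(cohort).groups.items():
        vals = v.loc[idx]
        ok = vals.notna()
        if ok.sum() == 0:
            raise ValueError(f"cohort {name!r} has no non-missing values")
        if ok.sum() < 2:
            raise ValueError(f"cohort {name!r} has fewer than 2 values")
        med = float(vals[ok].median())
        cutoffs[name] = med
        if vals[ok].nunique() == 1:
            warnings.warn(f"all values equal in cohort {name!r}; "
                          "all labelled Low", stacklevel=2)
        labels.loc[idx[ok]] = np.where(vals[ok] > med, "High", "Low")
    return labels.to_numpy(dtype=object), cutoffs


def combine_cd3(tc_status, im_status):
    """Combined CD3 stratum: CD3_High iff both TC and IM are High."""
    scalar = np.isscalar(tc_status)
    t = np.atleast_1d(np.asarray(tc_status, dtype=object))
    i = np.atleast_1d(np.asarray(im_status, dtype=object))
    if t.shape != i.shape:
        raise ValueError("statuses must align")
    bad = sorted({str(v) for v in np.concatenate([t, i])
                  if not pd.isna(v)} - {"Low", "High"})
    if bad:
        raise ValueError(f"statuses must be Low/High, got {bad}")
    out = np.empty(t.shape, dtype=object)
    for k in range(t.size):
        if pd.isna(t.flat[k]) or pd.isna(i.flat[k]):
            out.flat[k] = np.nan
        else:
            out.flat[k] = ("CD3_High" if (t.flat[k] == "High" and
                                          i.flat[k] == "High") else "CD3_Other")
    return out.item() if scalar else out
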