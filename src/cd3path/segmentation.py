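"""Tile classification and tumour-core / invasive-margin construction.

Tiles are classified into {tumour, stroma, background} by a pluggable,
seedable classifier (random forest by default).  Tumour tiles are rasterised
to pixel space, closed with a one-tile structuring element (fills single-tile
holes caused by classification noise), and 8-connected components below a
minimum surface are discarded; the surviving union is the tumour core (TC).
The invasive margin (IM) is the Euclidean-distance band
``0 < d(., TC) <= width_um / mpp`` around the TC, intersected with tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FEATURE_NAMES, FEATURE_REGISTRY_VERSION
from .imaging import TileFeatureTable, TileGrid

__all__ = [
    "CLASSES",
    "TileClassifier",
    "TileLabelMap",
    "RegionSet",
    "train_tile_classifier",
    "classify_tiles",
    "build_tumour_core",
    "build_invasive_margin",
    "build_regions",
    "DEFAULT_MARGIN_UM",
    "DEFAULT_MIN_TC_AREA_MM2",
]

log = logging.getLogger(__name__)

CLASSES = ("tumour", "stroma", "background")
DEFAULT_MARGIN_UM = 300.0
# "surface big enough" threshold for collating tumour tiles into the core;
# ~ a few hundred default-size tiles
DEFAULT_MIN_TC_AREA_MM2 = 1.0


class TrainingError(ValueError):
    pass


class RegistryMismatchError(ValueError):
    pass


@dataclass
class TileClassifier:
    """Fitted tile classifier plus its registry identity and accuracy."""

    model: RandomForestClassifier
    classes: tuple
    registry_version: str
    holdout_accuracy: float
    seed: int


@dataclass
class TileLabelMap:
    """Per-tile class labels with posterior probabilities."""

    table: pd.DataFrame        # columns: row, col, label, p_<class>...
    classes: tuple = CLASSES
    registry_version: str = FEATURE_REGISTRY_VERSION

    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


@dataclass
class RegionSet:
    """Tumour-core and invasive-margin masks in slide pixel space."""

    tc_mask: np.ndarray
    im_mask: np.ndarray
    mpp: float
    flags: dict = field(default_factory=dict)

    @property
    def tc_area_mm2(self) -> float:
        return float(self.tc_mask.sum()) * self.mpp**2 / 1e6

    @property
    def im_area_mm2(self) -> float:
        return float(self.im_mask.sum()) * self.mpp**2 / 1e6


def train_tile_classifier(features: TileFeatureTable | pd.DataFrame,
                          labels,
                          n_estimators: int = 200,
                          holdout_fraction: float = 0.25,
                          seed: int = 0,
                          **rf_kwargs) -> TileClassifier:
    """Fit the random-forest tile classifier with a held-out accuracy report.

    ``labels`` must contain at least two classes.  Deterministic given
    ``seed`` (both the holdout split and the forest are seeded).
    """
    X = features.matrix if isinstance(features, TileFeatureTable) else \
        features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise TrainingError("labels not aligned with features")
    if np.unique(y).size < 2:
        raise TrainingError("training labels contain a single class")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, **rf_kwargs
    )
    rf.fit(Xtr, ytr)
    acc = float((rf.predict(Xte) == yte).mean())
    return TileClassifier(
        model=rf,
        classes=tuple(rf.classes_),
        registry_version=FEATURE_REGISTRY_VERSION,
        holdout_accuracy=acc,
        seed=seed,
    )


def classify_tiles(clf: TileClassifier,
                   features: TileFeatureTable) -> TileLabelMap:
    """Label every tile of a feature table; probabilities attached."""
    if clf.registry_version != features.registry_version:
        raise RegistryMismatchError(
            f"classifier registry {clf.registry_version!r} != features "
            f"{features.registry_version!r}"
        )
    if len(features.table) == 0:
        cols = ["row", "col", "label"] + [f"p_{c}" for c in clf.classes]
        return TileLabelMap(table=pd.DataFrame(columns=cols))
    proba = clf.model.predict_proba(features.matrix)
    labels = np.asarray(clf.classes)[np.argmax(proba, axis=1)]
    out = features.table[["row", "col"]].copy()
    out["label"] = labels
    for j, c in enumerate(clf.classes):
        out[f"p_{c}"] = proba[:, j]
    return TileLabelMap(table=out, classes=clf.classes,
                        registry_version=features.registry_version)


def _tile_raster(label_map: TileLabelMap, grid: TileGrid, shape,
                 which: str) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    s = grid.tile_size_px
    t = label_map.table
    sel = t[t["label"] == which]
    for r, c in zip(sel["row"], sel["col"]):
        mask[r * s:(r + 1) * s, c * s:(c + 1) * s] = True
    return mask


def build_tumour_core(label_map: TileLabelMap, grid: TileGrid,
                      slide_shape,
                      min_area_mm2: float = DEFAULT_MIN_TC_AREA_MM2,
                      mpp: float = 0.5) -> tuple:
    """Collate tumour tiles into the tumour core.

    Tumour tiles are rasterised, morphologically closed with a one-tile
    square element, 8-connected-component labelled, and components smaller
    than ``min_area_mm2`` discarded.  Returns ``(tc_mask, flags)``; an empty
    core is allowed and flagged.
    """
    s = grid.tile_size_px
    # tumour raster is tile-constant, so the one-tile closing and the
    # component filter run on the tile grid and are upscaled afterwards
    tgrid = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    t = label_map.table
    sel = t[t["label"] == "tumour"]
    tgrid[sel["row"].to_numpy(int), sel["col"].to_numpy(int)] = True
    closed = ndimage.binary_closing(tgrid, structure=np.ones((3, 3), bool))
    closed |= tgrid             # closing must never remove tumour tiles
    lab, n = ndimage.label(closed, structure=np.ones((3, 3), dtype=int))
    min_tiles = min_area_mm2 * 1e6 / (mpp**2 * s**2)
    tc = np.zeros(slide_shape, dtype=bool)
    kept = 0
    if n:
        sizes = np.bincount(lab.ravel())[1:]
        keep = np.where(sizes >= min_tiles)[0] + 1
        kept = keep.size
        if kept:
            tc_tiles = np.isin(lab, keep)
            up = np.kron(tc_tiles, np.ones((s, s), dtype=bool))
            tc[:up.shape[0], :up.shape[1]] = up
    flags = {"empty_tc": not tc.any(), "n_components_kept": int(kept),
             "n_components_total": int(n)}
    if flags["empty_tc"]:
        log.warning("no tumour core detected (min_area_mm2=%g)", min_area_mm2)
    return tc, flags


def build_invasive_margin(tc_mask: np.ndarray,
                          width_um: float = DEFAULT_MARGIN_UM,
                          mpp: float = 0.5,
                          tissue_mask: np.ndarray | None = None) -> np.ndarray:
    """Invasive margin: pixels with ``0 < d(., TC) <= width_um / mpp``.

    Distances are Euclidean (distance transform); the band is intersected
    with ``tissue_mask`` when given.  Raises on an empty tumour core.
    """
    tc_mask = np.asarray(tc_mask, dtype=bool)
    if not tc_mask.any():
        raise ValueError("empty tumour core: invasive margin undefined")
    d = ndimage.distance_transform_edt(~tc_mask)
    band = (d > 0) & (d <= width_um / mpp)
    if tissue_mask is not None:
        band &= np.asarray(tissue_mask, dtype=bool)
    return band


def build_regions(label_map: TileLabelMap, grid: TileGrid, slide_shape,
                  mpp: float,
                  min_area_mm2: float = DEFAULT_MIN_TC_AREA_MM2,
                  width_um: float = DEFAULT_MARGIN_UM) -> RegionSet:
    """Convenience: tumour core + invasive margin with tissue = non-background tiles."""
    tc, flags = build_tumour_core(label_map, grid, slide_shape,
                                  min_area_mm2=min_area_mm2, mpp=mpp)
    if tc.any():
        tissue = ~_tile_raster(label_map, grid, slide_shape, "background")
        im = build_invasive_margin(tc, width_um=width_um, mpp=mpp,
                                   tissue_mask=tissue)
    else:
        im = np.zeros(slide_shape, dtype=bool)
        warnings.warn("empty tumour core; slide not analysable", stacklevel=2)
    return RegionSet(tc_mask=tc, im_mask=im, mpp=mpp, flags=flags)
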