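"""Slide I/O, tiling and H-DAB colour deconvolution.

A slide is a plain 8-bit RGB raster with a microns-per-pixel (mpp) scale.
Optical density is defined per channel as ``OD = -log10((I + 1) / 256)`` and
stain separation projects the OD vector on a configurable H-DAB basis
(Ruifrok-Johnston vectors by default).  Tiling uses 0-based, half-open,
row-major tile boxes; a partially covered right/bottom remainder is dropped.

The per-tile feature bank lives in :mod:`cd3path.features` and is re-exported
here (``extract_tile_features``, ``FEATURE_NAMES``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .features import (  # noqa: F401  (re-exported per module surface)
    FEATURE_NAMES,
    FEATURE_REGISTRY_VERSION,
    extract_tile_features,
)

__all__ = [
    "SlideImage",
    "TileGrid",
    "TileFeatureTable",
    "StainPair",
    "HDAB_BASIS",
    "read_slide",
    "write_slide",
    "write_mask",
    "read_mask",
    "tile_slide",
    "deconvolve_hdab",
    "compose_od",
    "compute_tile_features",
    "export_registry",
    "FormatError",
]


class FormatError(ValueError):
    """Unreadable or non-RGB image input."""


def _normed(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Ruifrok-Johnston H-DAB stain vectors (unit OD-space directions); third row
# is the residual direction completing the basis.
_H = _normed([0.650, 0.704, 0.286])
_D = _normed([0.268, 0.570, 0.776])
_R = _normed(np.cross(_H, _D))
HDAB_BASIS = np.vstack([_H, _D, _R])


@dataclass
class SlideImage:
    """8-bit RGB raster with physical scale."""

    pixels: np.ndarray          # (H, W, 3) uint8
    mpp: float                  # microns per pixel
    slide_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError("slide must be an RGB (H, W, 3) raster")
        if px.dtype != np.uint8:
            raise FormatError("slide must be 8-bit")
        if not (self.mpp and self.mpp > 0):
            raise FormatError("mpp must be a positive number")
        self.pixels = px

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class TileGrid:
    """Non-overlapping, image-covering tile partition (remainder cropped).

    Boxes are half-open pixel rectangles ``[x, x+s) x [y, y+s)`` in
    row-major order.
    """

    tile_size_px: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self):
        return self.n_rows * self.n_cols

    def boxes(self):
        s = self.tile_size_px
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c, (c * s, r * s, (c + 1) * s, (r + 1) * s)

    def tile_pixels(self, slide: SlideImage, row: int, col: int) -> np.ndarray:
        s = self.tile_size_px
        return slide.pixels[row * s:(row + 1) * s, col * s:(col + 1) * s]

    def centre(self, row: int, col: int):
        s = self.tile_size_px
        return ((col + 0.5) * s, (row + 0.5) * s)


@dataclass
class TileFeatureTable:
    """Per-tile feature vectors with the frozen registry identity."""

    table: pd.DataFrame          # columns: row, col, f001..f124
    tile_size_px: int
    registry_version: str = FEATURE_REGISTRY_VERSION

    @property
    def matrix(self) -> np.ndarray:
        return self.table[list(FEATURE_NAMES)].to_numpy(dtype=float)


@dataclass
class StainPair:
    """Optical-density images of the separated stains."""

    h_od: np.ndarray
    dab_od: np.ndarray
    residual_od: np.ndarray
    basis: np.ndarray
    reconstruction_rmse: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_slide(path, mpp: float, slide_id: str | None = None) -> SlideImage:
    """Read a PNG/TIFF RGB slide. ``mpp`` must be supplied by the caller."""
    path = Path(path)
    if mpp is None:
        raise FormatError("mpp is required (no default configured)")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:                      # unreadable / undecodable
        raise IOError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path} is not an RGB image (shape {arr.shape})")
    arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise FormatError(f"{path} is not 8-bit")
    return SlideImage(pixels=arr, mpp=float(mpp),
                      slide_id=slide_id or path.stem)


def write_slide(slide: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, slide.pixels, compression=None)
    else:
        Image.fromarray(slide.pixels).save(path)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr).save(Path(path))


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim != 2:
        raise FormatError("mask files must be single-channel")
    return arr > 127


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_slide(slide: SlideImage, tile_size_px: int = 256) -> TileGrid:
    """Partition the slide into square tiles, dropping the remainder."""
    if tile_size_px < 32:
        raise ValueError("tile_size_px must be >= 32")
    h, w = slide.shape
    n_rows, n_cols = h // tile_size_px, w // tile_size_px
    if n_rows == 0 or n_cols == 0:
        raise ValueError(
            f"image {w}x{h} smaller than one {tile_size_px} px tile"
        )
    return TileGrid(tile_size_px=tile_size_px, n_rows=n_rows, n_cols=n_cols)


# ---------------------------------------------------------------------------
# colour deconvolution
# ---------------------------------------------------------------------------

def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density, ``-log10((I + 1) / 256)``."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def compose_od(od_rgb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (quantised to 8 bits)."""
    I = 256.0 * np.power(10.0, -np.asarray(od_rgb, dtype=float)) - 1.0
    return np.clip(np.rint(I), 0, 255).astype(np.uint8)


def deconvolve_hdab(pixels: np.ndarray, basis: np.ndarray = HDAB_BASIS) -> StainPair:
    """Project per-pixel OD on the H-DAB stain basis.

    Negative concentrations are clamped at zero; the reconstruction RMSE of
    the clamped solution against the observed OD image is reported.
    """
    od = rgb_to_od(np.asarray(pixels))
    inv = np.linalg.inv(basis)
    conc = od @ inv
    conc = np.maximum(conc, 0.0)
    recon = conc @ basis
    rmse = float(np.sqrt(np.mean((recon - od) ** 2)))
    return StainPair(
        h_od=conc[..., 0],
        dab_od=conc[..., 1],
        residual_od=conc[..., 2],
        basis=basis,
        reconstruction_rmse=rmse,
    )


# ---------------------------------------------------------------------------
# feature computation over a grid
# ---------------------------------------------------------------------------

def compute_tile_features(slide: SlideImage, grid: TileGrid,
                          basis: np.ndarray = HDAB_BASIS) -> TileFeatureTable:
    """Extract the 124-feature vector for every tile of the grid."""
    rows = []
    for r, c, _ in grid.boxes():
        tile = grid.tile_pixels(slide, r, c)
        stains = deconvolve_hdab(tile, basis)
        vec = extract_tile_features(tile, stains, slide.mpp)
        rows.append((r, c, *vec))
    table = pd.DataFrame(rows, columns=["row", "col", *FEATURE_NAMES])
    return TileFeatureTable(table=table, tile_size_px=grid.tile_size_px)


def export_registry(path) -> None:
    """Write the frozen feature registry (names + version) as JSON."""
    payload = {
        "version": FEATURE_REGISTRY_VERSION,
        "n_features": len(FEATURE_NAMES),
        "names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
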