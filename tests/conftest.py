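"""Shared fixtures: synthetic slides, tile features, a trained classifier.

Everything is generated programmatically and seeded; the expensive imaging
fixtures are session-scoped so the suite pays for them once.
"""

import numpy as np
import pandas as pd
import pytest

from cd3path import imaging, segmentation, simdata

TILE = 64


@pytest.fixture(scope="session")
def default_slide():
    """One 640 px synthetic H-DAB slide with ground truth."""
    params = simdata.SlideSimParams(width_px=640, height_px=640, mpp=1.0,
                                    seed=7)
    return simdata.generate_slide(params, slide_id="fixture-640")


@pytest.fixture(scope="session")
def slide_features(default_slide):
    slide, _ = default_slide
    grid = imaging.tile_slide(slide, TILE)
    feats = imaging.compute_tile_features(slide, grid)
    return grid, feats


def truth_tile_labels(truth, grid, tile=TILE):
    """Majority-pixel truth labels for every tile."""
    labels = []
    for r, c, _ in grid.boxes():
        tum = truth.tumour_mask[r * tile:(r + 1) * tile,
                                c * tile:(c + 1) * tile].mean()
        tis = truth.tissue_mask[r * tile:(r + 1) * tile,
                                c * tile:(c + 1) * tile].mean()
        labels.append("tumour" if tum > 0.5
                      else ("background" if tis < 0.3 else "stroma"))
    return np.asarray(labels)


@pytest.fixture(scope="session")
def tile_truth_labels(default_slide, slide_features):
    _, truth = default_slide
    grid, _ = slide_features
    return truth_tile_labels(truth, grid)


@pytest.fixture(scope="session")
def trained_classifier(slide_features, tile_truth_labels):
    _, feats = slide_features
    return segmentation.train_tile_classifier(feats, tile_truth_labels,
                                              seed=0)


@pytest.fixture(scope="session")
def toy_cohort():
    """Small PH cohort with one moderate binary effect (seeded)."""
    rng = np.random.default_rng(11)
    n = 160
    x = (rng.random(n) < 0.5).astype(float)
    te = rng.exponential(1 / (0.03 * np.exp(0.7 * x)))
    tc = np.minimum(rng.exponential(60, n), 60.0)
    time = np.minimum(te, tc)
    event = (te <= tc).astype(int)
    return pd.DataFrame({"time": time, "event": event, "x": x})
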