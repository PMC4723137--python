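"""Shared fixtures: synthetic study sets reused across test modules.

The heavyweight pipeline products (the 30-ROI training set and the two
whole-margin runs) are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from marginmap import (
    MSERConfig,
    assemble_mosaic,
    bin_features,
    margin_heatmap,
    mser_detect,
    partition_bins,
)
from marginmap import synthetic
from marginmap.mser import area_fraction

TRAIN_SEEDS = {"tumor": 0, "muscle": 1000, "adipose": 2000}
N_TRAIN_PER_CLASS = 10


def run_roi_pipeline(tissue: str, seed: int, config: MSERConfig | None = None):
    """Generate one ROI and run segmentation + binning; returns (img, regions, feats)."""
    img, gt = synthetic.gen_tissue_roi(tissue, seed=seed)
    regions = mser_detect(img, config or MSERConfig())
    grid = partition_bins(img.width_px, img.height_px)
    feats = bin_features(regions, grid, img.pitch_um)
    return img, regions, feats


@pytest.fixture(scope="session")
def training_set():
    """10 tumor + 10 muscle + 10 adipose ROIs -> per-bin features and labels."""
    feats, labels, area_fracs = [], [], {}
    for tissue, base in TRAIN_SEEDS.items():
        afs = []
        for i in range(N_TRAIN_PER_CLASS):
            img, regions, f = run_roi_pipeline(tissue, base + i)
            feats.extend(f)
            labels.extend([int(tissue == "tumor")] * len(f))
            afs.append(area_fraction(regions, img.shape))
        area_fracs[tissue] = afs
    return {
        "features": feats,
        "labels": np.array(labels),
        "area_fractions": area_fracs,
    }


def run_margin(patch_fraction: float, seed: int):
    tiles, offsets, gt = synthetic.gen_margin(
        layout=(2, 3), tumor_patch_fraction=patch_fraction, seed=seed
    )
    mosaic = assemble_mosaic(tiles, offsets)
    return margin_heatmap(mosaic), gt


@pytest.fixture(scope="session")
def negative_margin():
    """Tumor-free 2x3 margin (muscle + adipose tiles)."""
    return run_margin(0.0, seed=42)


@pytest.fixture(scope="session")
def positive_margin():
    """2x3 margin with a contiguous tumor patch over 25% of bins."""
    return run_margin(0.25, seed=43)
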