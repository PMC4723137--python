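"""Whole-margin mosaics, tumor-probability heatmaps, and positivity summaries.

A resected margin is covered by several stage-translated frames (typically a
2x2 or 2x3 grid, stage steps 1.3 mm in x and 1.8 mm in y). Frames are placed
at their physical offsets on a common canvas; where frames overlap, the
later-listed frame wins (painter's order — deterministic, and sufficient
because all analysis is bin-wise). The composite is then processed exactly
like a site image: MSER segmentation, 50x50-px binning, per-bin features and
logistic tumor probability, summarized as the fraction of bins whose
probability strictly exceeds a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .image import GrayImage, ImageError
from .features import BinGrid, BinFeatures, partition_bins, bin_features
from .classify import LogisticModel, predict_probs
from .mser import MSERConfig, Region, mser_detect

__all__ = [
    "MarginMosaic",
    "MarginHeatmap",
    "assemble_mosaic",
    "margin_heatmap",
    "margin_summary",
    "heatmap_to_dataframe",
    "render_heatmap_png",
]


@dataclass(frozen=True)
class MarginMosaic:
    """Composite margin raster plus the tiles and pixel offsets that built it."""

    composite: GrayImage
    offsets_px: tuple[tuple[int, int], ...]  # (row, col) top-left per tile
    tile_shapes: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MarginHeatmap:
    """Per-bin tumor probabilities over the composite's bin grid."""

    grid: BinGrid
    probabilities: np.ndarray  # (n_rows, n_cols) in [0, 1]
    features: tuple[BinFeatures, ...]
    regions: tuple[Region, ...]


def _um_to_px(offset_um: float, pitch_um: float) -> int:
    """Physical offset to pixels, round-half-up."""
    return int(np.floor(offset_um / pitch_um + 0.5))


def assemble_mosaic(
    tiles: Sequence[GrayImage],
    offsets_um: Sequence[tuple[float, float]],
    pitch_um: float | None = None,
) -> MarginMosaic:
    """Place tiles at (x_um, y_um) offsets on a zero canvas, painter's order."""
    if not tiles:
        raise ValueError("at least one tile required")
    if len(tiles) != len(offsets_um):
        raise ValueError("one (x_um, y_um) offset required per tile")
    pitch = pitch_um if pitch_um is not None else tiles[0].pitch_um
    for t in tiles:
        if t.pitch_um != pitch:
            raise ImageError(
                f"tile pitch {t.pitch_um} differs from mosaic pitch {pitch}"
            )
    px_offsets = []
    for x_um, y_um in offsets_um:
        if x_um < 0 or y_um < 0:
            raise ValueError("offsets must be non-negative")
        px_offsets.append((_um_to_px(y_um, pitch), _um_to_px(x_um, pitch)))
    height = max(r + t.height_px for (r, _), t in zip(px_offsets, tiles))
    width = max(c + t.width_px for (_, c), t in zip(px_offsets, tiles))
    canvas = np.zeros((height, width), dtype=np.uint8)
    for (r, c), t in zip(px_offsets, tiles):
        canvas[r : r + t.height_px, c : c + t.width_px] = t.pixels
    return MarginMosaic(
        composite=GrayImage(canvas, pitch),
        offsets_px=tuple(px_offsets),
        tile_shapes=tuple(t.shape for t in tiles),
    )


def margin_heatmap(
    mosaic: MarginMosaic,
    mser_config: MSERConfig | None = None,
    model: LogisticModel | None = None,
    bin_px: int = 50,
) -> MarginHeatmap:
    """Segment the composite, bin it, and score each bin's tumor probability."""
    from .classify import reference_model

    comp = mosaic.composite
    config = mser_config or MSERConfig()
    model = model or reference_model()
    regions = mser_detect(comp, config)
    grid = partition_bins(comp.width_px, comp.height_px, bin_px)
    feats = bin_features(regions, grid, comp.pitch_um)
    probs = predict_probs(model, feats, pitch_um=comp.pitch_um)
    pmat = probs.reshape(grid.n_rows, grid.n_cols)
    return MarginHeatmap(
        grid=grid,
        probabilities=pmat,
        features=tuple(feats),
        regions=tuple(regions),
    )


def margin_summary(heatmap: MarginHeatmap, threshold: float = 0.5) -> dict:
    """Fraction (and percent) of bins with probability strictly above threshold."""
    p = heatmap.probabilities
    if p.size == 0:
        raise ValueError("heatmap has no bins")
    n_above = int((p > threshold).sum())
    frac = n_above / p.size
    return {
        "threshold": float(threshold),
        "n_bins": int(p.size),
        "n_above": n_above,
        "fraction": frac,
        "percent": 100.0 * frac,
    }


def heatmap_to_dataframe(heatmap: MarginHeatmap) -> pd.DataFrame:
    rows = []
    for br in range(heatmap.grid.n_rows):
        for bc in range(heatmap.grid.n_cols):
            rows.append(
                {
                    "bin_row": br,
                    "bin_col": bc,
                    "probability": float(heatmap.probabilities[br, bc]),
                }
            )
    return pd.DataFrame(rows, columns=["bin_row", "bin_col", "probability"])


def render_heatmap_png(heatmap: MarginHeatmap, path: str, cmap: str = "inferno") -> None:
    """8-bit color render with a fixed colormap; the CSV carries the numbers."""
    import matplotlib

    matplotlib.use("Agg")
    from PIL import Image as PILImage

    rgba = matplotlib.colormaps[cmap](np.clip(heatmap.probabilities, 0, 1))
    rgb = (rgba[:, :, :3] * 255).astype(np.uint8)
    PILImage.fromarray(rgb, mode="RGB").save(path)
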