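"""Grayscale image container, file I/O, and structured-illumination demodulation.

Analysis images are 8-bit single-channel rasters with a known pixel pitch
(default 1.5 μm/px, the scale at which a 350x300 px region of interest spans
525x450 μm). Higher bit-depth inputs are linearly rescaled so the observed
maximum maps to 255; color images are rejected rather than silently converted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image as _PILImage

DEFAULT_PITCH_UM = 1.5


class ImageError(Exception):
    """Base class for image I/O and validation failures."""


class UnreadableImageError(ImageError):
    """The file could not be opened or decoded as TIFF/PNG."""


class MultiChannelImageError(ImageError):
    """The image has more than one channel; only grayscale is supported."""


class EmptyImageError(ImageError):
    """The image has zero pixels along some axis."""


@dataclass(frozen=True)
class GrayImage:
    """Single-channel 8-bit intensity raster with physical pixel pitch.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (height_px, width_px)
        Quantized intensities in [0, 255].
    pitch_um : float
        Physical size of one pixel in micrometers (> 0).
    """

    pixels: np.ndarray
    pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MultiChannelImageError(
                f"expected a 2-D single-channel raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise EmptyImageError(f"zero-size image: shape {px.shape}")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ImageError("GrayImage requires integer pixels; quantize first")
            if px.min() < 0 or px.max() > 255:
                raise ImageError("integer intensities outside [0, 255]")
            px = px.astype(np.uint8)
        if not self.pitch_um > 0:
            raise ImageError(f"pitch_um must be positive, got {self.pitch_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


def quantize(values: np.ndarray, pitch_um: float = DEFAULT_PITCH_UM) -> GrayImage:
    """Quantize a non-negative float raster to 8 bits.

    Linear map of [0, observed max] onto [0, 255] with round-half-up; an
    all-zero input stays all zero. Preserves relative contrast, which is what
    the 8-bit MSER stage assumes.
    """
    values = np.asarray(values, dtype=np.float64)
    values = np.clip(values, 0.0, None)
    vmax = values.max() if values.size else 0.0
    if vmax > 0:
        scaled = values * (255.0 / vmax)
    else:
        scaled = values
    return GrayImage(np.floor(scaled + 0.5).astype(np.uint8), pitch_um)


def clip_to_uint8(values: np.ndarray, pitch_um: float = DEFAULT_PITCH_UM) -> GrayImage:
    """Clip a float raster to [0, 255] and round-half-up (no rescaling)."""
    arr = np.clip(np.asarray(values, dtype=np.float64), 0.0, 255.0)
    return GrayImage(np.floor(arr + 0.5).astype(np.uint8), pitch_um)


def read_image(path: str | os.PathLike, pitch_um: float = DEFAULT_PITCH_UM) -> GrayImage:
    """Read a single-channel TIFF or PNG as a GrayImage.

    8-bit inputs pass through untouched; deeper integer inputs (12/16-bit) are
    linearly rescaled so the observed maximum maps to 255. Multi-channel images
    raise MultiChannelImageError: picking a channel is a scientific choice the
    caller must make explicitly.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise UnreadableImageError(f"no such file: {path}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            with _PILImage.open(path) as im:
                arr = np.asarray(im)
    except ImageError:
        raise
    except Exception as exc:  # decoding failure of either backend
        raise UnreadableImageError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise MultiChannelImageError(
            f"{path}: expected single-channel image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise EmptyImageError(f"{path}: zero-size image, shape {arr.shape}")
    if arr.dtype == np.uint8:
        return GrayImage(arr, pitch_um)
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnreadableImageError(f"{path}: unsupported dtype {arr.dtype}")
    vmax = int(arr.max())
    if vmax <= 255:
        return GrayImage(arr.astype(np.uint8), pitch_um)
    scaled = arr.astype(np.float64) * (255.0 / vmax)
    return GrayImage(np.floor(scaled + 0.5).astype(np.uint8), pitch_um)


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write an 8-bit grayscale TIFF or PNG (format from the extension)."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image.pixels)
    else:
        _PILImage.fromarray(image.pixels, mode="L").save(path)


def sim_demodulate(i0: GrayImage, i1: GrayImage, i2: GrayImage) -> GrayImage:
    """Optically section three phase-shifted structured-illumination frames.

    The frames carry a projected sinusoid at nominal phases 0, 2π/3, 4π/3; the
    in-focus (modulated) component is recovered with the standard three-phase
    root-mean-square-of-differences estimator

        S = (sqrt(2)/3) * sqrt((i0-i1)^2 + (i1-i2)^2 + (i2-i0)^2),

    which for frames c + m*cos(θ + φ_k) returns exactly the modulation
    amplitude m, independent of the unmodulated background c. Computed per
    pixel in floating point, then quantized to 8 bits (observed max → 255).
    """
    if not (i0.shape == i1.shape == i2.shape):
        raise ImageError(
            f"phase frames differ in shape: {i0.shape}, {i1.shape}, {i2.shape}"
        )
    s = sim_demodulate_float(
        i0.pixels.astype(np.float64),
        i1.pixels.astype(np.float64),
        i2.pixels.astype(np.float64),
    )
    return quantize(s, i0.pitch_um)


def sim_demodulate_float(a0: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Float-valued square-law demodulation (no quantization)."""
    a0 = np.asarray(a0, dtype=np.float64)
    a1 = np.asarray(a1, dtype=np.float64)
    a2 = np.asarray(a2, dtype=np.float64)
    return (np.sqrt(2.0) / 3.0) * np.sqrt(
        (a0 - a1) ** 2 + (a1 - a2) ** 2 + (a2 - a0) ** 2
    )
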