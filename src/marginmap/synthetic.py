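"""Seeded synthetic phantoms: tissue ROIs, bead fields, margins, SIM stacks.

The generators emulate the qualitative appearance of acridine-orange-stained
sarcoma margin images so the whole analysis pipeline can be exercised and
validated without microscope data:

* tumor    — many nuclei (420 per 350x300 ROI) scattered over a smoothly
             varying mid-level background (dense cellular tissue);
* muscle   — few nuclei (40 per ROI) confined to the dark septa between
             bright ~75-um-wide fiber bands (AO stains the fibers strongly);
* adipose  — sparse nuclei (25 per ROI) sitting on the thin bright
             connective-tissue borders of dark polygonal adipocytes.

Nuclei are drawn as uniform disks with diameters inside the biologically
expected 5-20 um range, the scene is blurred with an isotropic Gaussian of
4.4 um FWHM standing in for the system point-spread function, Gaussian read
noise is added, and the result is quantized to 8 bits. All generators are
pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import GrayImage, clip_to_uint8

__all__ = [
    "TissueParams",
    "TISSUE_DEFAULTS",
    "GroundTruth",
    "gen_tissue_roi",
    "gen_bead_phantom",
    "gen_margin",
    "gen_sim_stack",
    "ROI_WIDTH_PX",
    "ROI_HEIGHT_PX",
    "FRAME_WIDTH_PX",
    "FRAME_HEIGHT_PX",
    "STEP_X_UM",
    "STEP_Y_UM",
]

ROI_WIDTH_PX = 350
ROI_HEIGHT_PX = 300
#: full camera frame (raster at the 1.5 um/px analysis scale)
FRAME_WIDTH_PX = 1376
FRAME_HEIGHT_PX = 1040
#: stage translation between adjacent margin frames
STEP_X_UM = 1300.0
STEP_Y_UM = 1800.0

DEFAULT_BLUR_FWHM_UM = 4.4
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TissueParams:
    """Appearance parameters of one tissue class.

    The class defaults (see :data:`TISSUE_DEFAULTS`) are the study
    conditions used throughout the tests and the acceptance analysis; they
    are deliberately kept in one place so every run is reproducible.
    """

    tissue: str  # tumor | muscle | adipose
    nuclei_per_roi: int
    diameter_range_um: tuple[float, float]
    nucleus_intensity: int = 200
    blur_fwhm_um: float = DEFAULT_BLUR_FWHM_UM
    noise_sd: float = 0.5
    flat_background: int | None = None  # overrides the class background model
    # class background knobs
    fiber_width_um: float = 75.0  # muscle band width
    septum_width_px: int = 5
    adipocyte_diameter_um: float = 120.0

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "muscle", "adipose"):
            raise ValueError(f"unknown tissue class {self.tissue!r}")
        lo, hi = self.diameter_range_um
        if not (5.0 <= lo <= hi <= 20.0):
            raise ValueError("nuclear diameters must lie within [5, 20] um")
        if self.nuclei_per_roi < 0:
            raise ValueError("nuclei_per_roi must be >= 0")


#: per-class defaults: nucleus counts give bin-level area fractions ordered
#: tumor >> adipose > muscle, mirroring the observed class separation
TISSUE_DEFAULTS: dict[str, TissueParams] = {
    "tumor": TissueParams("tumor", 420, (6.0, 14.0), nucleus_intensity=190),
    "muscle": TissueParams("muscle", 40, (5.0, 9.0), nucleus_intensity=210),
    "adipose": TissueParams("adipose", 25, (5.0, 9.0), nucleus_intensity=200),
}


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew (before blur/noise)."""

    centers: np.ndarray  # (n, 2) float (row, col) in px
    diameters_um: np.ndarray  # (n,)
    mask: np.ndarray  # bool, union of drawn disks
    bin_class: np.ndarray | None = None  # per-bin class labels (margins)
    meta: dict | None = None


def _disk_paint(canvas, mask, centers, radii_px, intensities) -> None:
    h, w = canvas.shape
    for (cr, cc), rad, inten in zip(centers, radii_px, intensities):
        r0, r1 = int(max(0, np.floor(cr - rad))), int(min(h - 1, np.ceil(cr + rad)))
        c0, c1 = int(max(0, np.floor(cc - rad))), int(min(w - 1, np.ceil(cc + rad)))
        if r1 < r0 or c1 < c0:
            continue
        rr, cc2 = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        disk = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= rad**2
        sub = canvas[r0 : r1 + 1, c0 : c1 + 1]
        sub[disk] = np.maximum(sub[disk], inten)
        mask[r0 : r1 + 1, c0 : c1 + 1] |= disk


def _tumor_background(shape, rng) -> np.ndarray:
    """Smoothly varying mid-level field (dense cellular tissue)."""
    field = rng.normal(size=shape)
    field = ndimage.gaussian_filter(field, sigma=25, mode="reflect")
    sd = field.std() or 1.0
    return 75.0 + 35.0 * field / sd


def _muscle_background(shape, pitch_um, params, rng) -> tuple[np.ndarray, np.ndarray]:
    """Bright vertical fiber bands separated by dark septa.

    Returns (background, septum mask); nuclei live on the septa (the fiber
    bundle periphery).
    """
    h, w = shape
    band_px = max(8, int(round(params.fiber_width_um / pitch_um)))
    sep_px = params.septum_width_px
    period = band_px + sep_px
    phase = rng.integers(0, period)
    cols = (np.arange(w) + phase) % period
    septum_cols = cols >= band_px
    bg = np.empty(shape)
    band_ids = ((np.arange(w) + phase) // period).astype(int)
    # integer band levels: a flat field sitting on a quantization boundary
    # would dither into salt-and-pepper at the 8-bit rounding step
    levels = {b: float(rng.integers(115, 151)) for b in np.unique(band_ids)}
    for b, lev in levels.items():
        bg[:, band_ids == b] = lev
    bg[:, septum_cols] = 35.0
    septum = np.zeros(shape, dtype=bool)
    septum[:, septum_cols] = True
    return bg, septum


def _adipose_background(shape, pitch_um, params, rng) -> tuple[np.ndarray, np.ndarray]:
    """Dark field with thin bright streaks along adipocyte borders.

    Borders are the ridges of a Voronoi tessellation of random cell sites;
    nuclei are placed on the borders.
    """
    h, w = shape
    cell_px = params.adipocyte_diameter_um / pitch_um
    n_sites = max(4, int(round(h * w / cell_px**2)))
    sites = np.column_stack(
        [rng.uniform(0, h, n_sites), rng.uniform(0, w, n_sites)]
    )
    from scipy.spatial import cKDTree

    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    dist, _ = cKDTree(sites).query(pts, k=2)
    border = ((dist[:, 1] - dist[:, 0]) < 1.5).reshape(h, w)
    # streak brightness varies smoothly along the septa, as connective
    # tissue does; constant-intensity ridges would read as strings of
    # compact nucleus-sized blobs after blur
    f = ndimage.gaussian_filter(rng.normal(size=shape), 12, mode="reflect")
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    bg = np.full(shape, 15.0)
    bg[border] = 50.0 + 80.0 * f[border]
    return bg, border


def _sample_on_mask(mask: np.ndarray, n: int, rng) -> np.ndarray:
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0 and n > 0:
        raise ValueError("no valid placement sites for the requested nuclei")
    pick = rng.choice(idx, size=n, replace=True)
    r, c = np.divmod(pick, mask.shape[1])
    jitter = rng.uniform(-1.0, 1.0, size=(n, 2))
    return np.column_stack([r, c]).astype(np.float64) + jitter


def gen_tissue_roi(
    params: TissueParams | str,
    width_px: int = ROI_WIDTH_PX,
    height_px: int = ROI_HEIGHT_PX,
    pitch_um: float = 1.5,
    seed: int = 0,
) -> tuple[GrayImage, GroundTruth]:
    """Render one tissue ROI: background, nuclei disks, PSF blur, noise, 8-bit.

    ``params`` may be a class name, which selects :data:`TISSUE_DEFAULTS`.
    Nucleus count is scaled by area when the canvas is not the standard
    350x300 ROI. Fully reproducible from (params, seed).
    """
    if isinstance(params, str):
        params = TISSUE_DEFAULTS[params]
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    scale = (width_px * height_px) / (ROI_WIDTH_PX * ROI_HEIGHT_PX)
    n = int(round(params.nuclei_per_roi * scale))

    placement: np.ndarray | None = None
    if params.flat_background is not None:
        bg = np.full(shape, float(params.flat_background))
    elif params.tissue == "tumor":
        bg = _tumor_background(shape, rng)
    elif params.tissue == "muscle":
        bg, placement = _muscle_background(shape, pitch_um, params, rng)
    else:
        bg, placement = _adipose_background(shape, pitch_um, params, rng)

    if placement is None:
        centers = np.column_stack(
            [rng.uniform(0, height_px, n), rng.uniform(0, width_px, n)]
        )
    else:
        centers = _sample_on_mask(placement, n, rng)
    lo, hi = params.diameter_range_um
    diams = rng.uniform(lo, hi, n)
    intens = params.nucleus_intensity + rng.uniform(-15, 15, n)

    canvas = bg.copy()
    mask = np.zeros(shape, dtype=bool)
    _disk_paint(canvas, mask, centers, diams / 2.0 / pitch_um, intens)

    sigma_px = params.blur_fwhm_um * _FWHM_TO_SIGMA / pitch_um
    canvas = ndimage.gaussian_filter(canvas, sigma=sigma_px, mode="reflect")
    if params.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sd, shape)
    img = clip_to_uint8(canvas, pitch_um)
    return img, GroundTruth(centers=centers, diameters_um=diams, mask=mask)


def gen_bead_phantom(
    diameter_um: float,
    n_beads: int,
    width_px: int = ROI_WIDTH_PX,
    height_px: int = ROI_HEIGHT_PX,
    pitch_um: float = 1.5,
    blur_fwhm_um: float = DEFAULT_BLUR_FWHM_UM,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[GrayImage, GroundTruth]:
    """Field of identical fluorescent beads on a dark background, non-touching."""
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    rad_px = diameter_um / 2.0 / pitch_um
    min_sep = 2 * rad_px + 2 * blur_fwhm_um / pitch_um + 4
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"cannot place {n_beads} non-touching beads of {diameter_um} um"
            )
        m = rad_px + 2
        cand = (
            rng.uniform(m, height_px - m),
            rng.uniform(m, width_px - m),
        )
        if all(
            (cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep**2 for r, c in centers
        ):
            centers.append(cand)
    centers_arr = np.array(centers).reshape(n_beads, 2)

    canvas = np.full(shape, 10.0)
    mask = np.zeros(shape, dtype=bool)
    _disk_paint(
        canvas,
        mask,
        centers_arr,
        np.full(n_beads, rad_px),
        np.full(n_beads, 220.0),
    )
    sigma_px = blur_fwhm_um * _FWHM_TO_SIGMA / pitch_um
    canvas = ndimage.gaussian_filter(canvas, sigma=sigma_px, mode="reflect")
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, shape)
    img = clip_to_uint8(canvas, pitch_um)
    gt = GroundTruth(
        centers=centers_arr,
        diameters_um=np.full(n_beads, float(diameter_um)),
        mask=mask,
    )
    return img, gt


def gen_margin(
    layout: tuple[int, int] = (2, 3),
    class_map: Sequence[str] | None = None,
    tumor_patch_fraction: float = 0.0,
    tile_width_px: int = FRAME_WIDTH_PX,
    tile_height_px: int = FRAME_HEIGHT_PX,
    pitch_um: float = 1.5,
    bin_px: int = 50,
    seed: int = 0,
) -> tuple[list[GrayImage], list[tuple[float, float]], GroundTruth]:
    """Synthesize a whole-margin acquisition: tiles + stage offsets + truth.

    One master scene at composite size is rendered (normal-tissue classes per
    tile footprint in painter's order, plus an optional contiguous tumor
    patch spanning full grid width from the top), then cut into tiles at the
    stage offsets, so overlapping tiles see identical sample content. The
    ground truth carries the per-bin true class over the composite bin grid
    ("none" where no tile covers the bin).

    layout = (nx, ny) frames; offsets are multiples of the stage steps
    (1300 um in x, 1800 um in y). tumor_patch_fraction is the requested
    fraction of all composite bins covered by the tumor patch.
    """
    nx, ny = layout
    if nx < 1 or ny < 1:
        raise ValueError("layout must have at least one tile per axis")
    if not 0.0 <= tumor_patch_fraction <= 1.0:
        raise ValueError("tumor_patch_fraction must be in [0, 1]")
    n_tiles = nx * ny
    if class_map is None:
        class_map = ["muscle", "adipose"] * ((n_tiles + 1) // 2)
    class_map = list(class_map)[:n_tiles]
    for c in class_map:
        if c not in ("muscle", "adipose", "tumor"):
            raise ValueError(f"unknown tile class {c!r}")

    rng = np.random.default_rng(seed)
    offsets_um = [
        (ix * STEP_X_UM, iy * STEP_Y_UM) for iy in range(ny) for ix in range(nx)
    ]
    offs_px = [
        (int(np.floor(y / pitch_um + 0.5)), int(np.floor(x / pitch_um + 0.5)))
        for x, y in offsets_um
    ]
    H = max(r for r, _ in offs_px) + tile_height_px
    W = max(c for _, c in offs_px) + tile_width_px

    # per-pixel base class, painter's order over tile footprints
    CLASS_NONE, CLASS_T, CLASS_M, CLASS_A = 0, 1, 2, 3
    code = {"tumor": CLASS_T, "muscle": CLASS_M, "adipose": CLASS_A}
    pixclass = np.full((H, W), CLASS_NONE, dtype=np.uint8)
    for (r, c), cls in zip(offs_px, class_map):
        pixclass[r : r + tile_height_px, c : c + tile_width_px] = code[cls]

    # contiguous tumor patch: full grid width, rows from the top
    n_rows, n_cols = H // bin_px, W // bin_px
    n_patch = int(round(tumor_patch_fraction * n_rows * n_cols))
    patch_rows = int(np.ceil(n_patch / n_cols)) if n_patch else 0
    covered_rows = 0
    while (covered_rows + 1) * bin_px <= tile_height_px:
        covered_rows += 1
    if patch_rows > covered_rows:
        raise ValueError(
            f"tumor patch of {patch_rows} bin rows exceeds the "
            f"{covered_rows} contiguous covered rows of the first tile band"
        )
    if patch_rows:
        pixclass[: patch_rows * bin_px, : n_cols * bin_px] = CLASS_T

    # render backgrounds per class over the full canvas, compose by mask
    canvas = np.zeros((H, W))
    canvas[pixclass == CLASS_T] = _tumor_background((H, W), rng)[pixclass == CLASS_T]
    mus_bg, septum = _muscle_background((H, W), pitch_um, TISSUE_DEFAULTS["muscle"], rng)
    canvas[pixclass == CLASS_M] = mus_bg[pixclass == CLASS_M]
    adi_bg, border = _adipose_background(
        (H, W), pitch_um, TISSUE_DEFAULTS["adipose"], rng
    )
    canvas[pixclass == CLASS_A] = adi_bg[pixclass == CLASS_A]

    mask = np.zeros((H, W), dtype=bool)
    all_centers, all_diams = [], []
    roi_px = ROI_WIDTH_PX * ROI_HEIGHT_PX
    for cls_code, cls_name, site_mask in (
        (CLASS_T, "tumor", None),
        (CLASS_M, "muscle", septum),
        (CLASS_A, "adipose", border),
    ):
        region = pixclass == cls_code
        area = int(region.sum())
        if area == 0:
            continue
        p = TISSUE_DEFAULTS[cls_name]
        n = int(round(p.nuclei_per_roi * area / roi_px))
        if n == 0:
            continue
        sites = region if site_mask is None else (region & site_mask)
        centers = _sample_on_mask(sites, n, rng)
        diams = rng.uniform(*p.diameter_range_um, n)
        intens = p.nucleus_intensity + rng.uniform(-15, 15, n)
        _disk_paint(canvas, mask, centers, diams / 2.0 / pitch_um, intens)
        all_centers.append(centers)
        all_diams.append(diams)

    sigma_px = DEFAULT_BLUR_FWHM_UM * _FWHM_TO_SIGMA / pitch_um
    canvas = ndimage.gaussian_filter(canvas, sigma=sigma_px, mode="reflect")
    canvas[pixclass == CLASS_NONE] = 0.0
    canvas = canvas + rng.normal(0.0, 0.5, (H, W))
    canvas[pixclass == CLASS_NONE] = 0.0
    scene = clip_to_uint8(canvas, pitch_um)

    tiles = [
        GrayImage(
            scene.pixels[r : r + tile_height_px, c : c + tile_width_px].copy(),
            pitch_um,
        )
        for r, c in offs_px
    ]

    # per-bin true class: majority pixel class within the bin
    names = np.array(["none", "tumor", "muscle", "adipose"])
    bin_class = np.empty((n_rows, n_cols), dtype=object)
    for br in range(n_rows):
        for bc in range(n_cols):
            blk = pixclass[br * bin_px : (br + 1) * bin_px, bc * bin_px : (bc + 1) * bin_px]
            bin_class[br, bc] = names[np.bincount(blk.ravel(), minlength=4).argmax()]

    gt = GroundTruth(
        centers=np.concatenate(all_centers) if all_centers else np.empty((0, 2)),
        diameters_um=np.concatenate(all_diams) if all_diams else np.empty(0),
        mask=mask,
        bin_class=bin_class,
        meta={"layout": layout, "class_map": class_map, "n_patch_bins": patch_rows * n_cols},
    )
    return tiles, offsets_um, gt


def gen_sim_stack(
    sectioned_truth: GrayImage,
    background_level: int = 20,
    modulation_period_px: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GrayImage, GrayImage, GrayImage]:
    """Three phase-shifted structured-illumination frames of a known scene.

    frame_k = background + truth * (1 + cos(2*pi*x/period + phi_k)) / 2,
    phi_k in {0, 2pi/3, 4pi/3}, plus optional Gaussian noise. The background
    stands for out-of-focus light, which square-law demodulation removes.
    Raises if background + max(truth) would clip at 255.
    """
    if int(background_level) != background_level or background_level < 0:
        raise ValueError("background_level must be a non-negative integer")
    truth = sectioned_truth.pixels.astype(np.float64)
    if background_level + truth.max() > 255:
        raise ValueError(
            "background_level + max(truth) exceeds 255; rescale the truth image"
        )
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    x = np.arange(w)[None, :]
    frames = []
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        modulation = (1.0 + np.cos(2.0 * np.pi * x / modulation_period_px + phi)) / 2.0
        f = background_level + truth * modulation
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, (h, w))
        frames.append(clip_to_uint8(f, sectioned_truth.pitch_um))
    return tuple(frames)


def measure_bead_diameters(
    regions,
    ground_truth: GroundTruth,
    pitch_um: float = 1.5,
    match_radius_px: float = 2.0,
) -> np.ndarray:
    """Per-bead equivalent diameter (um) from the innermost matched region.

    For each true bead center, the smallest detected region with a pixel
    within ``match_radius_px`` of the center is taken as that bead's
    segmentation (nested coarser regions are outer blur skirts). Beads with
    no matched region are skipped.
    """
    out = []
    for cr, cc in ground_truth.centers:
        areas = [
            r.area_px
            for r in regions
            if np.any(
                (np.abs(r.pixels[:, 0] - cr) < match_radius_px)
                & (np.abs(r.pixels[:, 1] - cc) < match_radius_px)
            )
        ]
        if areas:
            out.append(2.0 * np.sqrt(min(areas) / np.pi) * pitch_um)
    return np.array(out)
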