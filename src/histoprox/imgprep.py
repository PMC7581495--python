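"""Deterministic image standardization, patch-grid sampling and augmentation.

Every image entering the pipeline is white-balanced, rescaled so its shortest
side is 512 px and center-cropped to 512x512.  Hand-engineered features are
computed on the crop; the set representation samples 21 overlapping 224x224
patches from a 5x5 grid spanning the *full* rescaled image, so wide images
simply overlap less along x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

SHORT_SIDE = 512
PATCH = 224
GRID = 5
#: grid slots excluded from direct evaluation (odd-odd interior tiles).
#: The 21 kept slots still cover every pixel of the image; each dropped
#: tile's four grid-adjacent neighbours are all evaluated, so heatmap
#: imputation from the four nearest tiles is exact.
DROPPED_SLOTS = ((1, 1), (1, 3), (3, 1), (3, 3))
N_PATCHES = GRID * GRID - len(DROPPED_SLOTS)


class ImageReadError(ValueError):
    """Raised for non-RGB, corrupt or undersized input rasters."""


@dataclass(frozen=True)
class StandardImage:
    """White-balanced image rescaled to short side 512 plus its center crop."""

    full: np.ndarray
    crop512: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if min(self.full.shape[:2]) != SHORT_SIDE:
            raise ValueError("full image short side must be exactly 512")
        if self.crop512.shape != (SHORT_SIDE, SHORT_SIDE, 3):
            raise ValueError("crop512 must be 512x512x3")


@dataclass(frozen=True)
class PatchSet:
    """21 patches of 224x224x3 sampled from the 5x5 grid over the full image."""

    patches: np.ndarray  # (21, 224, 224, 3)
    offsets: np.ndarray  # (21, 2) top-left (row, col), 0-based
    grid_slots: tuple  # 21 (row, col) slots of the 5x5 grid

    def __post_init__(self) -> None:
        if len(self.patches) != N_PATCHES:
            raise ValueError(f"expected {N_PATCHES} patches")


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ImageReadError("expected a non-empty HxWx3 RGB raster")
    return image


def white_balance(image: np.ndarray) -> np.ndarray:
    """Gray-world white balance: rescale each channel to the global mean.

    Corrects global color casts (e.g. the blue shift of under-lit microscope
    photos).  A channel with zero mean is left untouched with a warning.
    """
    image = _as_rgb(image).astype(np.float64)
    channel_means = image.reshape(-1, 3).mean(axis=0)
    global_mean = channel_means.mean()
    out = image.copy()
    for c in range(3):
        if channel_means[c] == 0:
            warnings.warn(f"channel {c} has zero mean; white-balance gain skipped")
            continue
        out[:, :, c] *= global_mean / channel_means[c]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def standardize(image: np.ndarray, source_id: str = "") -> StandardImage:
    """White-balance, rescale so min(H, W) = 512 (bilinear, aspect kept,
    long side rounded half-up) and extract the central 512x512 crop
    (centering offset floored when odd)."""
    image = _as_rgb(image)
    h, w = image.shape[:2]
    if min(h, w) < 64:
        raise ImageReadError(f"image {h}x{w} too small; min side must be >= 64")
    image = white_balance(image)
    if min(h, w) != SHORT_SIDE:
        scale = SHORT_SIDE / min(h, w)
        if h <= w:
            new_h, new_w = SHORT_SIDE, _round_half_up(w * scale)
        else:
            new_h, new_w = _round_half_up(h * scale), SHORT_SIDE
        full = resize(
            image.astype(np.float64),
            (new_h, new_w),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        full = np.clip(np.rint(full), 0, 255).astype(np.uint8)
    else:
        full = image
    fh, fw = full.shape[:2]
    r0 = (fh - SHORT_SIDE) // 2
    c0 = (fw - SHORT_SIDE) // 2
    crop = full[r0 : r0 + SHORT_SIDE, c0 : c0 + SHORT_SIDE]
    return StandardImage(full=full, crop512=crop.copy(), source_id=source_id)


def grid_offsets(height: int, width: int) -> np.ndarray:
    """All 25 top-left offsets of the 5x5 patch grid for an image of the
    given size, row-major, as an (5, 5, 2) integer array."""
    rows = np.floor(np.linspace(0, height - PATCH, GRID) + 0.5).astype(int)
    cols = np.floor(np.linspace(0, width - PATCH, GRID) + 0.5).astype(int)
    out = np.empty((GRID, GRID, 2), dtype=int)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            out[i, j] = (r, c)
    return out


def patch_grid(std: StandardImage) -> PatchSet:
    """Sample the 21 evaluated 224x224 patches of the 5x5 grid over the full
    image.  Deterministic in (H, W) only; the union of the 21 patches covers
    the entire image."""
    full = std.full
    h, w = full.shape[:2]
    if min(h, w) != SHORT_SIDE:
        raise ValueError("full image short side must be 512")
    offs = grid_offsets(h, w)
    slots = tuple(
        (i, j)
        for i in range(GRID)
        for j in range(GRID)
        if (i, j) not in DROPPED_SLOTS
    )
    patches = np.empty((len(slots), PATCH, PATCH, 3), dtype=full.dtype)
    offsets = np.empty((len(slots), 2), dtype=int)
    for k, (i, j) in enumerate(slots):
        r, c = offs[i, j]
        patches[k] = full[r : r + PATCH, c : c + PATCH]
        offsets[k] = (r, c)
    return PatchSet(patches=patches, offsets=offsets, grid_slots=slots)


@dataclass
class AugmentConfig:
    """Training-time augmentation magnitudes (8-bit pixel scale).

    Defaults: right-angle rotation, +/-15 deg small rotation with reflect
    padding, flips, zoom in [0.9, 1.1], brightness gain in [0.9, 1.1],
    Gaussian noise sigma 2.5, Mixup Beta(0.2).
    """

    p_rot90: float = 0.5
    p_small_rotation: float = 0.5
    max_small_rotation: float = 15.0
    p_flip: float = 0.5
    p_zoom: float = 0.5
    zoom_range: tuple = (0.9, 1.1)
    p_brightness: float = 0.5
    brightness_range: tuple = (0.9, 1.1)
    noise_sigma: float = 2.5
    mixup_alpha: float = 0.2

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(
            p_rot90=0.0,
            p_small_rotation=0.0,
            max_small_rotation=0.0,
            p_flip=0.0,
            p_zoom=0.0,
            zoom_range=(1.0, 1.0),
            p_brightness=0.0,
            brightness_range=(1.0, 1.0),
            noise_sigma=0.0,
            mixup_alpha=0.0,
        )


def _zoom(patch: np.ndarray, factor: float) -> np.ndarray:
    size = patch.shape[0]
    new = max(8, _round_half_up(size * factor))
    scaled = resize(patch, (new, new), order=1, anti_aliasing=False, preserve_range=True)
    if new >= size:
        r0 = (new - size) // 2
        return scaled[r0 : r0 + size, r0 : r0 + size]
    pad = size - new
    before = pad // 2
    return np.pad(
        scaled, ((before, pad - before), (before, pad - before), (0, 0)), mode="reflect"
    )


def augment(
    patch: np.ndarray,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
    mix_with: np.ndarray | None = None,
):
    """Apply the augmentation chain in fixed order; returns ``(patch, lam)``
    where ``lam`` is the Mixup weight of the primary patch (None when no
    ``mix_with`` partner is supplied)."""
    cfg = config or AugmentConfig()
    out = patch.astype(np.float64)
    if rng.random() < cfg.p_rot90:
        out = np.rot90(out, k=int(rng.integers(1, 4)))
    if rng.random() < cfg.p_small_rotation and cfg.max_small_rotation > 0:
        angle = rng.uniform(-cfg.max_small_rotation, cfg.max_small_rotation)
        out = rotate(out, angle, mode="reflect", order=1, preserve_range=True)
    if rng.random() < cfg.p_flip:
        out = out[::-1]
    if rng.random() < cfg.p_flip:
        out = out[:, ::-1]
    if rng.random() < cfg.p_zoom:
        out = _zoom(out, rng.uniform(*cfg.zoom_range))
    if rng.random() < cfg.p_brightness:
        out = out * rng.uniform(*cfg.brightness_range)
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, out.shape)
    lam = None
    if mix_with is not None and cfg.mixup_alpha > 0:
        lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
        out = lam * out + (1.0 - lam) * mix_with.astype(np.float64)
    elif mix_with is not None:
        lam = 1.0
    return np.clip(out, 0, 255), lam
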