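"""Slide and micrograph preprocessing: Otsu foreground segmentation and
256x256 patch tiling.

Bone marrow smears are dark material on a bright-field background, so
foreground is everything *below* the Otsu threshold of the grayscale
image, computed at a 16x downsampled resolution to keep segmentation
cheap.  Tiling enumerates patch windows on a stride grid over the level-0
canvas and keeps a window when enough of it is foreground.  Micrographs
(plain camera fields rather than pyramidal scans) are rescaled to an
effective 10x magnification and tiled exhaustively with edge padding, so
each micrograph yields a complete small bag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SlideRecord",
    "ForegroundMask",
    "TileSet",
    "otsu_threshold",
    "segment_foreground",
    "tile_foreground",
    "micrograph_to_patches",
    "extract_patches",
    "load_image",
]

DEFAULT_PATCH = 256
DEFAULT_DOWNSAMPLE = 16


@dataclass
class SlideRecord:
    slide_id: str
    path: Path
    label: int = -1
    source: str = "micrograph"  # {"wsi", "micrograph"}
    objective_magnification: float = 10.0

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.objective_magnification <= 0:
            raise ValueError("magnification must be positive")


@dataclass
class ForegroundMask:
    """Binary tissue mask at a downsampled resolution plus the level-0
    canvas size it describes."""

    grid: np.ndarray               # bool, ceil(H/f) x ceil(W/f)
    downsample_factor: int
    level0_size: tuple[int, int]   # (width, height) in level-0 pixels

    def __post_init__(self) -> None:
        w, h = self.level0_size
        f = self.downsample_factor
        expect = (math.ceil(h / f), math.ceil(w / f))
        if self.grid.shape != expect:
            raise ValueError(f"grid shape {self.grid.shape} != {expect} "
                             f"for level-0 size {self.level0_size} at {f}x")


@dataclass
class TileSet:
    """Kept patch windows: (x, y) top-left corners in 0-based level-0
    pixels; each window is the half-open square [x, x+P) x [y, y+P)."""

    slide_id: str
    coords: np.ndarray  # n x 2 int64
    patch_size: int = DEFAULT_PATCH
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.coords) != len({tuple(c) for c in self.coords.tolist()}):
            raise ValueError("duplicate tile coordinates")

    def __len__(self) -> int:
        return len(self.coords)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold of a 256-bin intensity histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split into bins ``<= t`` versus ``> t``; ties broken by the smallest
    ``t``.  Raises on a degenerate (single-bin) histogram.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonempty bins")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # counts in class <= t
    total = w0[-1]
    s0 = np.cumsum(hist * levels)             # intensity mass in class <= t
    w1 = total - w0
    s_total = s0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (s_total - s0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    # argmax takes the first (smallest-t) maximizer
    return int(np.argmax(var_between[:255]))


def _to_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        gray = image.astype(np.float64)
    elif image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"cannot interpret image of shape {image.shape}")
    return np.clip(gray, 0, 255)


def _block_mean_downsample(gray: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample with edge padding so the output has
    ceil(H/f) x ceil(W/f) cells and edge cells average only real pixels'
    replicated values (no zero bias)."""
    if factor == 1:
        return gray
    h, w = gray.shape
    ph = (-h) % factor
    pw = (-w) % factor
    padded = np.pad(gray, ((0, ph), (0, pw)), mode="edge")
    hh, ww = padded.shape
    return padded.reshape(hh // factor, factor, ww // factor, factor).mean(axis=(1, 3))


def segment_foreground(
    image: np.ndarray,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
) -> ForegroundMask:
    """Otsu-based tissue segmentation at a downsampled resolution.

    The image is block-mean downsampled, converted to grayscale
    luminance, and Otsu-thresholded; foreground is the dark class
    (pixels at or below the threshold).  A constant image yields an
    empty mask with a warning rather than an error.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[:2]
    gray = _to_grayscale(image)
    small = _block_mean_downsample(gray, downsample_factor)
    small_u8 = np.clip(np.round(small), 0, 255).astype(np.uint8)
    hist = np.bincount(small_u8.ravel(), minlength=256).astype(np.int64)
    if np.count_nonzero(hist) < 2:
        warnings.warn("constant image: empty foreground mask", stacklevel=2)
        grid = np.zeros_like(small_u8, dtype=bool)
    else:
        t = otsu_threshold(hist)
        grid = small_u8 <= t
    return ForegroundMask(grid=grid, downsample_factor=downsample_factor,
                          level0_size=(w, h))


def _stride(patch_size: int, overlap_fraction: float) -> int:
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = int(round(patch_size * (1.0 - overlap_fraction)))
    return max(stride, 1)


def window_foreground_fraction(mask: ForegroundMask, x: int, y: int,
                               patch_size: int) -> float:
    """Foreground fraction of the level-0 window [x, x+P) x [y, y+P),
    evaluated as the mean of the mask cells it touches."""
    f = mask.downsample_factor
    xs, xe = x // f, math.ceil((x + patch_size) / f)
    ys, ye = y // f, math.ceil((y + patch_size) / f)
    return float(mask.grid[ys:ye, xs:xe].mean())


def tile_foreground(
    mask: ForegroundMask,
    patch_size: int = DEFAULT_PATCH,
    overlap_fraction: float = 0.0,
    min_foreground_fraction: float = 0.5,
    slide_id: str = "",
) -> TileSet:
    """Enumerate patch windows on the stride grid and keep those whose
    foreground fraction (on the mask) reaches ``min_foreground_fraction``.

    Stride is ``round(patch_size * (1 - overlap_fraction))``.  Partial
    windows beyond the right/bottom edge are not emitted (tissue slides
    have abundant interior windows); coordinates are level-0 pixels.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    w, h = mask.level0_size
    stride = _stride(patch_size, overlap_fraction)
    if w < patch_size or h < patch_size:
        warnings.warn("canvas smaller than one patch: zero tiles", stacklevel=2)
        return TileSet(slide_id=slide_id, coords=np.empty((0, 2), dtype=np.int64),
                       patch_size=patch_size, overlap_fraction=overlap_fraction)
    # integral image of the mask for O(1) window sums
    grid = mask.grid.astype(np.int64)
    integral = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=np.int64)
    integral[1:, 1:] = grid.cumsum(0).cumsum(1)
    f = mask.downsample_factor
    coords = []
    for y in range(0, h - patch_size + 1, stride):
        ys, ye = y // f, math.ceil((y + patch_size) / f)
        for x in range(0, w - patch_size + 1, stride):
            xs, xe = x // f, math.ceil((x + patch_size) / f)
            count = (integral[ye, xe] - integral[ys, xe]
                     - integral[ye, xs] + integral[ys, xs])
            frac = count / ((ye - ys) * (xe - xs))
            if frac >= min_foreground_fraction:
                coords.append((x, y))
    return TileSet(slide_id=slide_id,
                   coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
                   patch_size=patch_size, overlap_fraction=overlap_fraction)


def extract_patches(image: np.ndarray, tiles: TileSet,
                    pad_color: tuple[int, int, int] = (236, 233, 228)
                    ) -> np.ndarray:
    """Cut the tiles' windows out of a level-0 image as an
    (n, P, P, 3) uint8 stack, padding any out-of-canvas region with
    ``pad_color``."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=2)
    h, w = image.shape[:2]
    p = tiles.patch_size
    out = np.empty((len(tiles), p, p, 3), dtype=np.uint8)
    for i, (x, y) in enumerate(tiles.coords):
        patch = np.empty((p, p, 3), dtype=np.uint8)
        patch[:] = pad_color
        xe, ye = min(x + p, w), min(y + p, h)
        patch[: ye - y, : xe - x] = image[y:ye, x:xe, :3]
        out[i] = patch
    return out


def micrograph_to_patches(
    image: np.ndarray,
    source_magnification: float,
    target_magnification: float = 10.0,
    patch_size: int = DEFAULT_PATCH,
    background_rgb: tuple[int, int, int] = (236, 233, 228),
    slide_id: str = "",
) -> tuple[TileSet, np.ndarray]:
    """Rescale a micrograph to the target magnification and tile it
    exhaustively into a complete padded grid of patches (one bag per
    micrograph).

    The scale factor is ``target / source``; partial right/bottom
    windows are padded with the background color so every patch is full
    size.  Coordinates refer to the rescaled canvas.
    """
    if source_magnification < target_magnification:
        raise ValueError("source magnification below target")
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=2)
    scale = target_magnification / source_magnification
    h, w = image.shape[:2]
    nh, nw = max(int(round(h * scale)), 1), max(int(round(w * scale)), 1)
    if scale != 1.0:
        image = np.asarray(
            Image.fromarray(image[..., :3]).resize((nw, nh), Image.BILINEAR))
    if image.size == 0:
        raise ValueError("rescaled image is empty")
    nx, ny = math.ceil(nw / patch_size), math.ceil(nh / patch_size)
    xs, ys = np.meshgrid(np.arange(nx) * patch_size, np.arange(ny) * patch_size)
    coords = np.stack([xs.ravel(), ys.ravel()], axis=1)
    tiles = TileSet(slide_id=slide_id, coords=coords, patch_size=patch_size,
                    overlap_fraction=0.0)
    patches = extract_patches(image, tiles, pad_color=background_rgb)
    return tiles, patches


def load_image(path: str | Path) -> np.ndarray:
    """Read a flat image (PNG/JPEG/TIFF) as an H x W x 3 uint8 array.
    For multi-page TIFFs the first (highest-resolution) page is used."""
    img = Image.open(path).convert("RGB")
    return np.asarray(img, dtype=np.uint8)
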