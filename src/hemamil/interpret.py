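"""Attention heatmaps: localize the model's diagnostic evidence.

The slide is re-tiled at 50% overlap, each patch is encoded and scored
with one class branch's attention, the raw scores are min-max normalized
to [0, 1] across the slide's patches, and every pixel of the map takes
the *mean* normalized score of all patches covering it.  Maps are built
at the segmentation downsample (16x by default), which matches the
display resolution such overlays are read at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .features import Encoder
from .mil import GatedAttentionMIL
from .preprocess import (DEFAULT_DOWNSAMPLE, DEFAULT_PATCH, TileSet,
                         extract_patches, segment_foreground, tile_foreground)

__all__ = [
    "Heatmap",
    "attention_heatmap",
    "heatmap_from_scores",
    "normalize_scores",
    "evidence_localization_score",
    "render_overlay",
]


@dataclass
class Heatmap:
    """Per-pixel normalized attention at a stated downsample.

    ``values`` are meaningful only where ``coverage`` is set (covered by
    at least one patch); uncovered pixels are flagged, not zero-filled.
    """

    values: np.ndarray      # float in [0, 1] where covered
    coverage: np.ndarray    # bool
    downsample_factor: int
    class_index: int
    overlap_fraction: float = 0.5


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max normalize attention scores to [0, 1] across a slide's
    patches; a degenerate slide (all scores equal) maps to 0.5."""
    s = np.asarray(scores, dtype=np.float64)
    lo, hi = s.min(), s.max()
    if hi - lo < 1e-300:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def heatmap_from_scores(
    coords: np.ndarray,
    scores: np.ndarray,
    level0_size: tuple[int, int],
    patch_size: int = DEFAULT_PATCH,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    class_index: int = -1,
    overlap_fraction: float = 0.5,
    normalized: bool = False,
) -> Heatmap:
    """Accumulate per-patch attention scores into an overlap-averaged map.

    Each patch paints its normalized score over its window at the map
    resolution; pixels covered by several patches average their scores.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if coords.shape[0] != scores.size:
        raise ValueError("coords and scores must align")
    w, h = level0_size
    f = downsample_factor
    gh, gw = -(-h // f), -(-w // f)
    acc = np.zeros((gh, gw))
    cnt = np.zeros((gh, gw), dtype=np.int64)
    norm = scores if normalized else normalize_scores(scores)
    for (x, y), s in zip(coords, norm):
        xs, xe = x // f, min(-(-(x + patch_size) // f), gw)
        ys, ye = y // f, min(-(-(y + patch_size) // f), gh)
        acc[ys:ye, xs:xe] += s
        cnt[ys:ye, xs:xe] += 1
    coverage = cnt > 0
    values = np.zeros((gh, gw))
    values[coverage] = acc[coverage] / cnt[coverage]
    return Heatmap(values=values, coverage=coverage,
                   downsample_factor=f, class_index=class_index,
                   overlap_fraction=overlap_fraction)


def attention_heatmap(
    image: np.ndarray,
    estimator: GatedAttentionMIL,
    encoder: Encoder,
    class_index: int | None = None,
    overlap_fraction: float = 0.5,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    min_foreground_fraction: float = 0.5,
    patch_size: int = DEFAULT_PATCH,
) -> tuple[Heatmap, TileSet, np.ndarray]:
    """End-to-end heatmap for one slide image.

    Tiles the foreground at ``overlap_fraction`` (50% by default for a
    fine-grained map), encodes the patches, scores them with the chosen
    class branch's attention (default: the predicted class), min-max
    normalizes and overlap-averages.  Returns the heatmap plus the tile
    set and the normalized per-patch scores.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    mask = segment_foreground(image, downsample_factor)
    tiles = tile_foreground(mask, patch_size=patch_size,
                            overlap_fraction=overlap_fraction,
                            min_foreground_fraction=min_foreground_fraction)
    if len(tiles) == 0:
        warnings.warn("zero foreground patches: empty heatmap", stacklevel=2)
        empty = Heatmap(values=np.zeros(mask.grid.shape),
                        coverage=np.zeros(mask.grid.shape, dtype=bool),
                        downsample_factor=downsample_factor,
                        class_index=-1, overlap_fraction=overlap_fraction)
        return empty, tiles, np.empty(0)
    patches = extract_patches(image, tiles)
    bag = encoder.encode(patches)
    res = estimator.forward(bag)
    if class_index is None:
        class_index = int(np.argmax(res.probs))
    norm = normalize_scores(res.A[class_index])
    hm = heatmap_from_scores(tiles.coords, norm, (w, h),
                             patch_size=patch_size,
                             downsample_factor=downsample_factor,
                             class_index=class_index,
                             overlap_fraction=overlap_fraction,
                             normalized=True)
    return hm, tiles, norm


def evidence_localization_score(scores: np.ndarray, evidence_flags) -> float:
    """Rank agreement between attention and ground-truth evidence.

    Area under the ROC of the attention score against the binary
    evidence flag: 1.0 when every evidence instance out-scores every
    background instance, 0.5 when attention is uninformative.
    """
    from sklearn.metrics import roc_auc_score

    flags = np.asarray(evidence_flags).astype(bool)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if flags.size != scores.size or flags.size == 0:
        raise ValueError("scores and flags must align")
    if flags.all() or not flags.any():
        raise ValueError("localization undefined: bag is all-evidence or "
                         "no-evidence")
    return float(roc_auc_score(flags.astype(int), scores))


def render_overlay(
    thumbnail: np.ndarray,
    heatmap: Heatmap,
    colormap: str = "jet",
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend the heatmap over a slide thumbnail (uint8 RGB output,
    deterministic for fixed inputs).  The thumbnail must match the
    heatmap grid shape."""
    import matplotlib

    thumb = np.asarray(thumbnail)
    if thumb.ndim == 2:
        thumb = np.repeat(thumb[..., None], 3, axis=2)
    if thumb.shape[:2] != heatmap.values.shape:
        raise ValueError(
            f"thumbnail {thumb.shape[:2]} does not match heatmap "
            f"{heatmap.values.shape}")
    colors = matplotlib.colormaps[colormap](np.clip(heatmap.values, 0, 1))[..., :3]
    blended = thumb.astype(np.float64) / 255.0
    cov = heatmap.coverage
    blended[cov] = (1 - alpha) * blended[cov] + alpha * colors[cov]
    return np.clip(np.round(blended * 255), 0, 255).astype(np.uint8)


def save_heatmap(heatmap: Heatmap, path) -> None:
    """Store values + coverage as a compressed npz."""
    np.savez_compressed(path, values=heatmap.values,
                        coverage=heatmap.coverage,
                        downsample_factor=heatmap.downsample_factor,
                        class_index=heatmap.class_index,
                        overlap_fraction=heatmap.overlap_fraction)


def heatmap_to_png(heatmap: Heatmap, path) -> None:
    """Render the raw map as a grayscale PNG (uncovered pixels black)."""
    img = np.zeros(heatmap.values.shape, dtype=np.uint8)
    img[heatmap.coverage] = np.round(
        heatmap.values[heatmap.coverage] * 255).astype(np.uint8)
    Image.fromarray(img).save(path)
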