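"""Patch feature encoding and feature-bag I/O.

Each 256x256 RGB patch is mapped to a fixed-length feature vector
(1024-d by default) by a pluggable encoder applied frozen — the encoder
is never trained, so a slide's bag of features can be computed once and
reused.  The shipped encoder is fully deterministic and dependency-light:
it mean-pools the patch on an 8x8 grid and applies a fixed seeded linear
map, which preserves the coarse spatial color layout that separates the
synthetic fixtures while requiring no pretrained weights.  Heavier
learned encoders plug in through the same :class:`Encoder` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Encoder",
    "PooledLinearEncoder",
    "FeatureBag",
    "encode_bag",
    "get_encoder",
    "load_bag",
    "save_bag",
]

PATCH_SIZE = 256


@dataclass
class FeatureBag:
    """A slide's bag: K instance feature vectors with level-0 patch
    coordinates and the slide-level label (-1 when unknown)."""

    slide_id: str
    features: np.ndarray  # K x D float32
    coords: np.ndarray    # K x 2 int64 (x, y) top-left, level-0 pixels
    label: int = -1
    magnification: int = 10
    encoder_name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.coords = np.asarray(self.coords)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a nonempty K x D matrix")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must be K x 2 and row-aligned with features")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite entries")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


class Encoder:
    """Contract for patch encoders: map a batch of ``(n, P, P, 3)`` uint8
    patches to an ``(n, output_dim)`` float32 matrix, deterministically
    when :attr:`deterministic` is set."""

    name: str = "base"
    output_dim: int = 1024
    deterministic: bool = True

    def encode(self, patches: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return self.encode(patches)


class PooledLinearEncoder(Encoder):
    """Deterministic test encoder: 8x8 mean pooling + fixed linear map.

    The patch is scaled to [0, 1], mean-pooled to an 8x8x3 grid (192
    values) and projected by a seeded Gaussian matrix scaled by
    ``1/sqrt(192)``.  Same patch always gives the same vector.
    """

    def __init__(self, output_dim: int = 1024, seed: int = 17,
                 pool_grid: int = 8):
        self.name = f"pooled-linear-{output_dim}d"
        self.output_dim = int(output_dim)
        self.deterministic = True
        self.pool_grid = int(pool_grid)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        n_in = 3 * self.pool_grid ** 2
        # kept in float64 so the map is exact to well below float32
        # resolution regardless of batch chunking
        self._weight = rng.standard_normal((n_in, self.output_dim)) / np.sqrt(n_in)

    def encode(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        n, h, w, c = patches.shape
        g = self.pool_grid
        if c != 3 or h % g or w % g:
            raise ValueError(
                f"patches must be (n, H, W, 3) with H, W divisible by {g}; "
                f"got {patches.shape}")
        x = patches.astype(np.float64) / 255.0
        pooled = x.reshape(n, g, h // g, g, w // g, 3).mean(axis=(2, 4))
        return (pooled.reshape(n, -1) @ self._weight).astype(np.float32)


_ENCODERS = {
    "test": PooledLinearEncoder,
    "pooled-linear": PooledLinearEncoder,
}
# the dependency-free encoder doubles as the default: no pretrained
# weights ship with the package
_ENCODERS["default"] = PooledLinearEncoder


def get_encoder(name: str = "default", **kwargs) -> Encoder:
    """Instantiate a registered encoder by name."""
    try:
        cls = _ENCODERS[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; available: "
                       f"{sorted(_ENCODERS)}") from None
    return cls(**kwargs)


def encode_bag(
    patches: np.ndarray,
    coords: np.ndarray,
    encoder: Encoder,
    slide_id: str = "",
    label: int = -1,
    magnification: int = 10,
    batch_size: int = 256,
) -> FeatureBag:
    """Encode a slide's patches into a feature bag.

    The encoder runs frozen; ``batch_size`` only chunks the computation
    and has no effect on the output.
    """
    patches = np.asarray(patches)
    if patches.ndim != 4 or patches.shape[0] < 1:
        raise ValueError("empty bag" if patches.size == 0 or patches.ndim < 4
                         or patches.shape[0] < 1 else "bad patch array")
    if patches.shape[3] != 3:
        raise ValueError(f"patches must be (n, H, W, 3); got {patches.shape}")
    chunks = [encoder.encode(patches[i:i + batch_size])
              for i in range(0, patches.shape[0], batch_size)]
    feats = np.concatenate(chunks, axis=0).astype(np.float32)
    return FeatureBag(slide_id=slide_id, features=feats,
                      coords=np.asarray(coords, dtype=np.int64),
                      label=label, magnification=magnification,
                      encoder_name=encoder.name)


def save_bag(bag: FeatureBag, path: str | Path) -> Path:
    """Write a bag as HDF5: datasets "features" (K x D float32) and
    "coords" (K x 2 int64); attrs slide_id, label, magnification,
    encoder_name."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=bag.features.astype(np.float32))
        fh.create_dataset("coords", data=bag.coords.astype(np.int64))
        fh.attrs["slide_id"] = bag.slide_id
        fh.attrs["label"] = int(bag.label)
        fh.attrs["magnification"] = int(bag.magnification)
        fh.attrs["encoder_name"] = bag.encoder_name
    return path


def load_bag(path: str | Path) -> FeatureBag:
    """Read a bag written by :func:`save_bag`; ``save o load`` is the
    identity on (features, coords, label, slide_id)."""
    with h5py.File(path, "r") as fh:
        for name in ("features", "coords"):
            if name not in fh:
                raise KeyError(f"bag file {path} missing dataset {name!r}")
        feats = np.asarray(fh["features"], dtype=np.float32)
        coords = np.asarray(fh["coords"], dtype=np.int64)
        if feats.ndim != 2:
            raise ValueError(f"'features' must be 2-D, got shape {feats.shape}")
        if coords.shape != (feats.shape[0], 2):
            raise ValueError(
                f"'coords' shape {coords.shape} does not match features "
                f"{feats.shape}")
        return FeatureBag(
            slide_id=str(fh.attrs.get("slide_id", Path(path).stem)),
            features=feats,
            coords=coords,
            label=int(fh.attrs.get("label", -1)),
            magnification=int(fh.attrs.get("magnification", 10)),
            encoder_name=str(fh.attrs.get("encoder_name", "")),
        )
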