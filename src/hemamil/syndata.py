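"""Synthetic feature bags and pseudo-slides with known ground truth.

The generator emulates the statistical structure the MIL classifier
assumes: each slide is a bag of instance feature vectors in which a small
"evidence" minority is drawn from a class-specific Gaussian displaced from
a shared background Gaussian, while everything else is background.
Pseudo-slide images emulate bright-field bone marrow smears as dark
cell-like blobs on a bright background, with a pixel mask marking the
evidence blobs, so the full preprocessing + attention pipeline can be
exercised end to end without any real slide.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .features import FeatureBag

__all__ = [
    "SyntheticBagSpec",
    "SyntheticSlideSpec",
    "GroundTruth",
    "PseudoSlide",
    "generate_feature_bags",
    "generate_pseudo_slide",
    "save_bags",
    "save_pseudo_slides",
    "evidence_directions",
]


@dataclass(frozen=True)
class SyntheticBagSpec:
    """Parameters of the generative model for synthetic feature bags.

    Background instances are drawn from ``N(mu_bg, noise_sd^2 I)`` and the
    evidence instances of class ``c`` from ``N(mu_bg + separation * u_c,
    noise_sd^2 I)`` where the ``u_c`` are fixed orthonormal directions, so
    every pair of classes sits at equal distance ``separation * sqrt(2)``
    in feature space while sharing the same background.
    """

    n_classes: int = 5
    bags_per_class: int = 10
    bag_size_range: tuple[int, int] = (30, 70)
    evidence_fraction: float = 0.10
    feature_dim: int = 1024
    separation: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        k_min, k_max = self.bag_size_range
        if not (1 <= k_min <= k_max):
            raise ValueError(f"invalid bag_size_range {self.bag_size_range}")
        if not (0.0 < self.evidence_fraction <= 1.0):
            raise ValueError("evidence_fraction must lie in (0, 1]")
        if self.evidence_fraction * k_min < 1.0:
            raise ValueError("bag too small for evidence fraction")
        if self.n_classes < 1 or self.feature_dim < 1:
            raise ValueError("n_classes and feature_dim must be positive")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.n_classes > self.feature_dim:
            raise ValueError("need feature_dim >= n_classes for orthonormal "
                             "evidence directions")


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of the pseudo-slide image generator.

    The background is a bright near-white field; blobs are dark filled
    disks.  Evidence blobs take the class color and are clustered inside a
    randomly placed region; distractor blobs are neutral dark gray spread
    over the whole canvas with the given density per 10^4 px^2.
    """

    canvas_size: tuple[int, int] = (1024, 1024)  # (width, height)
    background_rgb: tuple[int, int, int] = (236, 233, 228)
    blob_radius_range: tuple[int, int] = (8, 20)
    blobs_per_class_region: int = 25
    evidence_color_by_class: tuple[tuple[int, int, int], ...] = (
        (90, 30, 110),   # AML
        (40, 60, 130),   # ALL
        (130, 40, 50),   # CML
        (35, 100, 80),   # CLL
        (120, 90, 30),   # MM
    )
    distractor_rgb: tuple[int, int, int] = (105, 100, 110)
    distractor_density: float = 0.15  # blobs per 10^4 px^2
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.canvas_size
        if w < 1 or h < 1:
            raise ValueError("canvas must be nonempty")
        r_min, r_max = self.blob_radius_range
        if not (1 <= r_min <= r_max):
            raise ValueError("invalid blob_radius_range")
        bg_lum = _luminance(self.background_rgb)
        blob_lums = [_luminance(c) for c in self.evidence_color_by_class]
        blob_lums.append(_luminance(self.distractor_rgb))
        if bg_lum <= max(blob_lums):
            raise ValueError("background luminance must exceed every blob "
                             "luminance (Otsu separability)")


@dataclass
class GroundTruth:
    """Known truth for one synthetic bag: its label and which instances
    carry the class signal."""

    bag_label: int
    evidence_flags: np.ndarray  # bool, one per instance


@dataclass
class PseudoSlide:
    """A generated pseudo-slide image plus its evidence-pixel mask and the
    list of drawn blobs ``(cx, cy, r, is_evidence)`` for analytic checks."""

    slide_id: str
    label: int
    image: np.ndarray           # H x W x 3 uint8
    evidence_mask: np.ndarray   # H x W bool
    blobs: list[tuple[int, int, int, bool]] = field(default_factory=list)


def _luminance(rgb: tuple[int, int, int]) -> float:
    r, g, b = rgb
    return 0.299 * r + 0.587 * g + 0.114 * b


def evidence_directions(spec: SyntheticBagSpec) -> np.ndarray:
    """Fixed orthonormal evidence directions, one row per class.

    Drawn as the Q factor of a seeded Gaussian matrix; the seed is derived
    from ``spec.seed`` so that bags and directions are jointly reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD1E]))
    raw = rng.standard_normal((spec.feature_dim, spec.n_classes))
    q, r = np.linalg.qr(raw)
    # fix the sign convention so the basis is unique given the seed
    q = q * np.sign(np.diag(r))
    return q.T.astype(np.float64)


def generate_feature_bags(
    spec: SyntheticBagSpec,
    split_sizes: tuple[int, ...] | None = None,
    id_prefix: str = "synth",
):
    """Generate labeled feature bags with per-instance evidence flags.

    Bag sizes are uniform on ``bag_size_range``; each bag of class ``c``
    contains ``ceil(evidence_fraction * K)`` evidence instances and the
    rest background.  With ``split_sizes`` (e.g. ``(25, 8, 8)`` bags per
    class for train/val/test) the return value is one list of
    ``(FeatureBag, GroundTruth)`` pairs per split, all drawn from the
    same generative model — in particular the evidence directions
    ``u_c`` are shared across splits, as they must be for a model
    trained on one split to generalize to another.  Without it, a single
    list of ``spec.bags_per_class`` bags per class is returned.  Output
    is bit-identical for a fixed spec (the seed covers all randomness).
    """
    sizes = (spec.bags_per_class,) if split_sizes is None else tuple(split_sizes)
    if any(int(s) < 1 for s in sizes):
        raise ValueError("every split must hold >= 1 bag per class")
    dirs = evidence_directions(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA6]))
    k_min, k_max = spec.bag_size_range
    splits: list[list[tuple[FeatureBag, GroundTruth]]] = []
    for si, n_per_class in enumerate(sizes):
        out: list[tuple[FeatureBag, GroundTruth]] = []
        for label in range(spec.n_classes):
            for j in range(int(n_per_class)):
                k = int(rng.integers(k_min, k_max + 1))
                n_ev = math.ceil(spec.evidence_fraction * k)
                flags = np.zeros(k, dtype=bool)
                flags[rng.choice(k, size=n_ev, replace=False)] = True
                x = rng.standard_normal((k, spec.feature_dim)) * spec.noise_sd
                x[flags] += spec.separation * dirs[label]
                # pseudo patch coordinates on a tile grid (row-major, 256 px)
                idx = np.arange(k)
                coords = np.stack([(idx % 8) * 256, (idx // 8) * 256], axis=1)
                bag = FeatureBag(
                    slide_id=f"{id_prefix}_s{si}_c{label}_b{j:03d}",
                    features=x.astype(np.float32),
                    coords=coords.astype(np.int64),
                    label=label,
                    magnification=10,
                )
                out.append((bag, GroundTruth(bag_label=label,
                                             evidence_flags=flags)))
        splits.append(out)
    return splits[0] if split_sizes is None else splits


def generate_pseudo_slide(
    spec: SyntheticSlideSpec,
    label: int,
    slide_id: str | None = None,
    patch_size: int = 256,
) -> PseudoSlide:
    """Render one pseudo-slide: bright background, dark blobs, and an
    evidence mask marking the pixels of the label's blobs.

    The evidence blobs are clustered in a randomly placed rectangular
    region covering ~1/4 of the canvas; distractors are scattered
    everywhere.  Rendering is deterministic for a fixed spec + label.
    """
    w, h = spec.canvas_size
    if w < patch_size or h < patch_size:
        raise ValueError(
            f"canvas {spec.canvas_size} smaller than one {patch_size} px patch")
    if not (0 <= label < len(spec.evidence_color_by_class)):
        raise ValueError(f"label {label} has no evidence color")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, label, 0x51D]))

    img = Image.new("RGB", (w, h), tuple(spec.background_rgb))
    draw = ImageDraw.Draw(img)
    mask_img = Image.new("1", (w, h), 0)
    mask_draw = ImageDraw.Draw(mask_img)
    blobs: list[tuple[int, int, int, bool]] = []
    r_min, r_max = spec.blob_radius_range

    # distractors over the whole canvas
    n_distract = rng.poisson(spec.distractor_density * w * h / 1e4)
    for _ in range(int(n_distract)):
        r = int(rng.integers(r_min, r_max + 1))
        cx = int(rng.integers(r, w - r)) if w > 2 * r else w // 2
        cy = int(rng.integers(r, h - r)) if h > 2 * r else h // 2
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=tuple(spec.distractor_rgb))
        blobs.append((cx, cy, r, False))

    # evidence region: a half-width, half-height window placed at random
    if spec.blobs_per_class_region > 0:
        rw, rh = max(w // 2, 2 * r_max + 1), max(h // 2, 2 * r_max + 1)
        x0 = int(rng.integers(0, max(w - rw, 0) + 1))
        y0 = int(rng.integers(0, max(h - rh, 0) + 1))
        color = tuple(spec.evidence_color_by_class[label])
        for _ in range(spec.blobs_per_class_region):
            r = int(rng.integers(r_min, r_max + 1))
            cx = x0 + int(rng.integers(r, rw - r))
            cy = y0 + int(rng.integers(r, rh - r))
            cx, cy = min(cx, w - 1 - r), min(cy, h - 1 - r)
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color)
            mask_draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=1)
            blobs.append((cx, cy, r, True))

    image = np.asarray(img, dtype=np.uint8)
    evidence_mask = np.asarray(mask_img, dtype=bool)
    if spec.blobs_per_class_region > 0 and not evidence_mask.any():
        raise RuntimeError("evidence mask unexpectedly empty")
    sid = slide_id or f"pseudo_c{label}_s{spec.seed}"
    return PseudoSlide(slide_id=sid, label=label, image=image,
                       evidence_mask=evidence_mask, blobs=blobs)


def save_bags(
    bags: list[tuple[FeatureBag, GroundTruth]],
    out_dir: str | Path,
    truth_csv: str = "ground_truth.csv",
) -> Path:
    """Write one HDF5 file per bag plus a sidecar ground-truth CSV
    (slide_id, instance_index, evidence_flag).  Returns the CSV path."""
    from .features import save_bag

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / truth_csv
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "instance_index", "evidence_flag"])
        for bag, truth in bags:
            save_bag(bag, out / f"{bag.slide_id}.h5")
            for i, flag in enumerate(truth.evidence_flags):
                writer.writerow([bag.slide_id, i, int(flag)])
    return csv_path


def save_pseudo_slides(
    slides: list[PseudoSlide],
    out_dir: str | Path,
    manifest_csv: str = "manifest.csv",
    magnification: int = 10,
) -> Path:
    """Write each pseudo-slide as PNG + mask PNG and a manifest CSV
    (slide_id, path, label, magnification).  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / manifest_csv
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "path", "label", "magnification"])
        for s in slides:
            img_path = out / f"{s.slide_id}.png"
            Image.fromarray(s.image).save(img_path)
            Image.fromarray(s.evidence_mask.astype(np.uint8) * 255).save(
                out / f"{s.slide_id}_mask.png")
            writer.writerow([s.slide_id, img_path.name, s.label, magnification])
    return manifest
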