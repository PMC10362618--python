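"""Synthetic histology-like tiles with irregular low-contrast lesion blobs.

Real inputs are hematoxylin-eosin stained tissue tiles in which metastatic
regions appear as irregular, low-contrast areas of slightly different hue.
The generator emulates those statistics: a pink-ish textured background, one
or more star-convex blobs with Fourier-perturbed boundaries recolored toward
a purple-ish foreground mean by a configurable contrast gap, plus pixel noise.
Everything is seeded and bit-reproducible, and the on-disk layout
(``<root>/{train,test}/{images,masks}/NNNN.png`` + ``manifest.json``) accepts
drop-in real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon


@dataclass
class SynthConfig:
    tile_size: int = 96
    n_train: int = 40
    n_test: int = 10
    blobs_per_tile: tuple = (1, 3)
    blob_radius: tuple = (8, 20)
    irregularity: float = 0.35  # Fourier perturbation amplitude (fraction of radius)
    background_mean: tuple = (225, 190, 215)  # eosin-like pink
    foreground_shift: tuple = (-0.62, -0.71, -0.33)  # unit direction toward hematoxylin purple
    contrast_gap: float = 40.0  # |mean color difference| along the shift direction
    texture_sigma: float = 10.0  # smooth stain texture amplitude
    noise_sigma: float = 6.0  # per-pixel noise
    seed: int = 0

    def __post_init__(self):
        if self.tile_size % 8:
            raise ValueError("tile size must be divisible by 8")
        if self.contrast_gap < 0:
            raise ValueError("contrast gap must be >= 0")


@dataclass
class SegSample:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W uint8, values {0, 255}


def _star_blob(size: int, cx: float, cy: float, radius: float, irregularity: float, rng) -> np.ndarray:
    """Rasterize a star-convex blob with a Fourier-perturbed radius profile."""
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    r = np.full_like(theta, radius)
    for k in range(2, 6):  # low-order harmonics give lobed, irregular outlines
        amp = irregularity * radius * rng.uniform(0.1, 0.5) / k
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    r = np.clip(r, 2.0, None)
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def make_sample(cfg: SynthConfig, rng: np.random.Generator) -> SegSample:
    """One tile: textured background, recolored blobs, noise."""
    n = cfg.tile_size
    mask = np.zeros((n, n), dtype=bool)
    n_blobs = int(rng.integers(cfg.blobs_per_tile[0], cfg.blobs_per_tile[1] + 1))
    placed = 0
    while placed < n_blobs:
        radius = rng.uniform(*cfg.blob_radius)
        cx = rng.uniform(radius, n - radius)
        cy = rng.uniform(radius, n - radius)
        blob = _star_blob(n, cx, cy, radius, cfg.irregularity, rng)
        if not blob.any():  # degenerate rasterization: draw again
            continue
        mask |= blob
        placed += 1
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = np.asarray(cfg.background_mean, dtype=np.float64)
    # smooth multiplicative-looking stain texture shared across channels
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(n, n)), sigma=6)
    sd = texture.std()
    if sd > 0:
        img += (texture / sd * cfg.texture_sigma)[:, :, None]
    shift = np.asarray(cfg.foreground_shift, dtype=np.float64)
    shift = shift / np.linalg.norm(shift)
    img[mask] += shift * cfg.contrast_gap
    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return SegSample(
        image=np.clip(img, 0, 255).astype(np.uint8),
        mask=(mask.astype(np.uint8) * 255),
    )


def split_sizes(n_total: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Train/test sizes for an n-sample pool: ceil(f*n) train, the rest test."""
    n_train = int(np.ceil(train_fraction * n_total))
    return n_train, n_total - n_train


def generate_dataset(cfg: SynthConfig, root) -> dict:
    """Write a seeded synthetic dataset to ``root``; returns the manifest.

    Layout: ``<root>/{train,test}/{images,masks}/NNNN.png``.  Identical seeds
    produce byte-identical files.
    """
    root = Path(root)
    rng = np.random.default_rng(cfg.seed)
    counts = {"train": cfg.n_train, "test": cfg.n_test}
    manifest = {"config": asdict(cfg), "splits": {}}
    for split, count in counts.items():
        img_dir = root / split / "images"
        mask_dir = root / split / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        names = []
        for i in range(count):
            sample = make_sample(cfg, rng)
            name = f"{i:04d}.png"
            Image.fromarray(sample.image).save(img_dir / name)
            Image.fromarray(sample.mask, mode="L").save(mask_dir / name)
            names.append(name)
        manifest["splits"][split] = names
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_sample(root, split: str, name: str) -> SegSample:
    root = Path(root)
    img = np.asarray(Image.open(root / split / "images" / name).convert("RGB"))
    mask = np.asarray(Image.open(root / split / "masks" / name).convert("L"))
    if img.shape[:2] != mask.shape:
        raise ValueError(f"image/mask size mismatch for {split}/{name}")
    return SegSample(image=img, mask=mask)


def list_split(root, split: str) -> list[str]:
    root = Path(root)
    manifest = root / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            names = json.load(fh)["splits"].get(split)
        if names is not None:
            return list(names)
    return sorted(p.name for p in (root / split / "images").glob("*.png"))


def augment(sample: SegSample, seed: int) -> SegSample:
    """Random flips and 90-degree rotations applied jointly to image and mask."""
    rng = np.random.default_rng(seed)
    img, mask = sample.image, sample.mask
    if rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        img, mask = img[::-1], mask[::-1]
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k, axes=(0, 1))
        mask = np.rot90(mask, k, axes=(0, 1))
    return SegSample(image=np.ascontiguousarray(img), mask=np.ascontiguousarray(mask))


def flip_horizontal(sample: SegSample) -> SegSample:
    return SegSample(
        image=np.ascontiguousarray(sample.image[:, ::-1]),
        mask=np.ascontiguousarray(sample.mask[:, ::-1]),
    )


def to_training_arrays(samples: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into float NCHW images in [0, 1] and N1HW binary masks."""
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    masks = np.stack([(s.mask > 127).astype(np.float32) for s in samples])
    return imgs.transpose(0, 3, 1, 2), masks[:, None, :, :]
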