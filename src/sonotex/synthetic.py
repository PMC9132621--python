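"""Two-class ultrasound-like image simulator.

The generator emulates the sonographic contrast the pipeline targets:
the "female" class carries 2-4 bright parallel curvilinear bands
(labia-like parallel lines, random orientation and spacing) while the
"male" class carries a dome-shaped bright blob with a midline echogenic
streak (phallus-like).  Both ride on a smooth random background with a
mild depth-attenuation gradient and are degraded by unit-mean gamma
multiplicative speckle (the fully developed speckle model) and a light
Gaussian blur.

``separability`` scales the amplitude of the class-specific structure:
0 makes the two classes identically distributed (background + speckle
only); 1 gives maximal structural contrast.  Everything is driven by a
single seeded generator, so a fixed seed reproduces the dataset
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SynthConfig", "SyntheticDataset", "speckle", "generate_dataset"]

CLASS_LINES = "female"
CLASS_BLOB = "male"


@dataclass(frozen=True)
class SynthConfig:
    """Simulation conditions.

    n_per_class: images per class.
    image_side: square image side in pixels.
    separability: in [0, 1]; amplitude of class-specific structure
        relative to the background (0 = exchangeable classes).
    speckle_looks: gamma shape of the multiplicative speckle
        (variance 1/looks); 4 is a realistic single-frame value.
    seed: master RNG seed.
    """

    n_per_class: int = 60
    image_side: int = 256
    separability: float = 0.7
    speckle_looks: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")


def speckle(img: np.ndarray, looks: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply by i.i.d. unit-mean Gamma(shape=looks) noise, clip to [0,1].

    Before clipping the expectation is preserved pointwise.
    """
    if looks <= 0:
        raise ValueError("looks must be positive")
    img = np.asarray(img, dtype=np.float64)
    g = rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    return np.clip(img * g, 0.0, 1.0)


def _background(rng: np.random.Generator, side: int) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 10)
    field = (field - field.mean()) / (field.std() + 1e-12)
    bg = 0.35 + 0.05 * field
    depth = np.linspace(0.0, 1.0, side)[:, None]
    return bg * (1.0 - 0.15 * depth)


def _coords(side: int):
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    return yy, xx


def _parallel_lines(rng: np.random.Generator, side: int, amp: float) -> np.ndarray:
    """2-4 bright parallel curvilinear bands at a random orientation."""
    n_lines = int(rng.integers(2, 5))
    theta = rng.uniform(0, np.pi)
    spacing = rng.uniform(0.045, 0.07) * side
    width = rng.uniform(1.5, 2.6)
    curvature = rng.uniform(-0.6, 0.6)
    cy = side * (0.5 + rng.uniform(-0.08, 0.08))
    cx = side * (0.5 + rng.uniform(-0.08, 0.08))
    yy, xx = _coords(side)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)   # across bands
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)  # along bands
    u_curved = u + curvature * v ** 2 / side
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * spacing
    bands = sum(np.exp(-((u_curved - o) ** 2) / (2 * width ** 2)) for o in offsets)
    extent = np.exp(-((v / (0.35 * side)) ** 2))
    return amp * bands * extent


def _dome_blob(rng: np.random.Generator, side: int, amp: float) -> np.ndarray:
    """Dome-shaped bright blob plus a midline echogenic streak."""
    cy = side * (0.5 + rng.uniform(-0.08, 0.08))
    cx = side * (0.5 + rng.uniform(-0.08, 0.08))
    sx = side * rng.uniform(0.10, 0.16)
    sy = side * rng.uniform(0.07, 0.12)
    yy, xx = _coords(side)
    dome = np.exp(-(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2) / 2)
    phi = rng.uniform(-0.25, 0.25)  # streak tilt from vertical, radians
    d = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    along = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    streak_w = rng.uniform(1.2, 2.0)
    streak = np.exp(-(d ** 2) / (2 * streak_w ** 2)) * np.exp(
        -((along / (0.28 * side)) ** 2))
    return amp * (0.8 * dome + 1.1 * streak)


@dataclass(frozen=True)
class SyntheticDataset:
    images: np.ndarray          # (n, side, side) float64 in [0, 1]
    labels: np.ndarray          # class name per image
    config: SynthConfig
    paths: list | None = None   # set when written to disk

    def __len__(self) -> int:
        return self.images.shape[0]


def generate_dataset(cfg: SynthConfig, out_dir: str | Path | None = None
                     ) -> SyntheticDataset:
    """Simulate ``2 * n_per_class`` images (lines class first).

    With ``out_dir`` set, 8-bit PNGs, a ``manifest.csv`` (path,label)
    readable by the imaging loader, and a JSON parameter sidecar are
    written alongside the in-memory arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    side = cfg.image_side
    amp = 0.45 * cfg.separability
    images = []
    labels = []
    for cls, struct_fn in ((CLASS_LINES, _parallel_lines), (CLASS_BLOB, _dome_blob)):
        for _ in range(cfg.n_per_class):
            img = _background(rng, side) + struct_fn(rng, side, amp)
            img = np.clip(img, 0.0, 1.0)
            img = gaussian_filter(img, sigma=1.0)
            img = speckle(img, cfg.speckle_looks, rng)
            images.append(img)
            labels.append(cls)
    ds = SyntheticDataset(images=np.stack(images), labels=np.array(labels),
                          config=cfg)
    if out_dir is None:
        return ds
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        p = out_dir / f"img_{i:04d}_{lab}.png"
        iio.imwrite(p, np.round(img * 255).astype(np.uint8))
        paths.append(p)
    pd.DataFrame({"path": [str(p) for p in paths], "label": ds.labels}).to_csv(
        out_dir / "manifest.csv", index=False)
    (out_dir / "params.json").write_text(json.dumps(asdict(cfg), indent=2))
    return SyntheticDataset(images=ds.images, labels=ds.labels, config=cfg,
                            paths=paths)
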