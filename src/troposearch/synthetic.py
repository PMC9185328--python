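"""Seeded generator of desk-scale K-class brain-like image datasets.

Each image is a grayscale "axial slice" cartoon: a bright elliptical cortical
ring around a dark central ventricle on a mid-gray background, plus additive
Gaussian noise.  The class signal is geometric, emulating atrophy grades: the
ventricle radius grows and the ring dims monotonically with the class index,
so mean ring intensity separates the extreme classes and a small CPU-trained
classifier can learn the task.  A controllable fraction of images is replaced
by pure speckle noise whose moments put the signal-to-noise ratio (mean/std)
below 1.1 by construction, well under the 1.15 cleaning threshold, with the
ground truth recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocessing import DatasetBundle, compute_snr

__all__ = ["SyntheticSpec", "generate", "write_image_tree", "DEFAULT_CLASS_NAMES"]

DEFAULT_CLASS_NAMES = (
    "MildDemented",
    "ModerateDemented",
    "NonDemented",
    "VeryMildDemented",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one synthetic dataset."""

    K: int = 4
    n_per_class: int = 25
    image_size: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.05
    noisy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.noisy_fraction < 1.0:
            raise ValueError("noisy_fraction must be in [0, 1)")
        if min(self.image_size) < 16:
            raise ValueError("image too small to render a brain ellipse")

    def class_names(self) -> list[str]:
        if self.K == len(DEFAULT_CLASS_NAMES):
            return list(DEFAULT_CLASS_NAMES)
        return [f"class_{c}" for c in range(self.K)]


_BACKGROUND = 0.35
_CORTEX = 0.72
_VENTRICLE = 0.12


def _render_brain(
    c: int, K: int, size: tuple[int, int], rng: np.random.Generator, sigma: float
) -> np.ndarray:
    H, W = size
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    grade = c / max(K - 1, 1)
    # outer brain ellipse with slight per-image jitter
    ay = 0.42 * H * rng.uniform(0.96, 1.04)
    ax = 0.36 * W * rng.uniform(0.96, 1.04)
    # ventricle radius grows with atrophy grade; ring dims slightly
    rv = (0.08 + 0.10 * grade) * min(H, W) * rng.uniform(0.92, 1.08)
    cortex = _CORTEX - 0.06 * grade
    outer = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    inner = (yy - cy) ** 2 + (xx - cx) ** 2 <= rv ** 2
    img = np.full((H, W), _BACKGROUND)
    img[outer] = cortex
    img[outer & inner] = _VENTRICLE
    img += rng.normal(0.0, sigma, (H, W))
    return np.clip(img, 0.0, 1.0)


def _render_noise(size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Speckle: mostly near-black with sparse bright pixels; SNR < 1.1."""
    H, W = size
    bright = rng.random((H, W)) < 0.15
    img = rng.uniform(0.0, 0.1, (H, W))
    img[bright] = rng.uniform(0.7, 1.0, int(bright.sum()))
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    """Snap to the 8-bit grid so in-memory data matches PNG round-trips."""
    return np.round(img * 255.0) / 255.0


def generate(spec: SyntheticSpec) -> tuple[DatasetBundle, pd.DataFrame]:
    """Generate a dataset bundle and its ground-truth manifest.

    The manifest has one row per image: filename, class name, the noisy flag,
    and the image's actual SNR.  Exactly ``round(noisy_fraction * n_total)``
    images are replaced by pure noise (their class label is kept so counts
    per class stay exact).
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.class_names()
    images: list[np.ndarray] = []
    labels: list[int] = []
    filenames: list[str] = []
    for c in range(spec.K):
        for i in range(spec.n_per_class):
            img = _render_brain(c, spec.K, spec.image_size, rng, spec.noise_sigma)
            images.append(_quantize(img)[:, :, np.newaxis])
            labels.append(c)
            filenames.append(f"{names[c]}/img_{i:04d}.png")
    total = len(images)
    n_noisy = int(round(spec.noisy_fraction * total))
    noisy_idx = rng.choice(total, size=n_noisy, replace=False) if n_noisy else np.array([], dtype=int)
    noisy = np.zeros(total, dtype=bool)
    for i in noisy_idx:
        images[int(i)] = _quantize(_render_noise(spec.image_size, rng))[:, :, np.newaxis]
        noisy[int(i)] = True
    bundle = DatasetBundle(
        images=images, labels=np.asarray(labels, dtype=int),
        class_names=names, paths=filenames,
    )
    manifest = pd.DataFrame(
        {
            "filename": filenames,
            "class": [names[c] for c in labels],
            "noisy": noisy,
            "snr": [compute_snr(img) for img in images],
        }
    )
    return bundle, manifest


def write_image_tree(
    bundle: DatasetBundle,
    directory,
    manifest: pd.DataFrame | None = None,
    overwrite: bool = False,
) -> Path:
    """Write the bundle as an 8-bit PNG class-per-folder tree.

    Refuses an existing non-empty directory unless ``overwrite`` is set.
    A manifest, when given, is written alongside as ``manifest.csv``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty")
    directory.mkdir(parents=True, exist_ok=True)
    for name in bundle.class_names:
        (directory / name).mkdir(exist_ok=True)
    counters = {name: 0 for name in bundle.class_names}
    for img, label in zip(bundle.images, bundle.labels):
        name = bundle.class_names[label]
        arr = np.round(np.asarray(img)[:, :, 0] * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(
            directory / name / f"img_{counters[name]:04d}.png"
        )
        counters[name] += 1
    if manifest is not None:
        manifest.to_csv(directory / "manifest.csv", index=False)
    return directory
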