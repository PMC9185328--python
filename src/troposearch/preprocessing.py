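"""Image-dataset preprocessing: cleaning, resizing, encoding, scaling, splitting.

Images are plain ``H x W x C`` float arrays with C of 1 (grayscale) or 3
(RGB).  The pipeline stages mirror a typical MRI-classification front end:

1. conversion (DICOM series or class-per-folder PNG/JPEG trees) and
   signal-to-noise cleaning — slices whose SNR (mean / std of pixel
   intensities) falls below a threshold, 1.15 by default, are discarded;
2. bicubic resizing to the network input size 128 x 128 x 3;
3. categorical label encoding (class name -> consecutive integer);
4. one of four pixel scaling techniques (normalize, standardize, min-max,
   max-abs);
5. a stratified train / validation / test split (15% test by default);
6. augmentation-based balancing of the training stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize, warp
from sklearn.model_selection import train_test_split

from .search_space import HyperparameterConfig

__all__ = [
    "DatasetBundle",
    "SCALING_TECHNIQUES",
    "scale",
    "resize_to_input",
    "compute_snr",
    "clean_dataset",
    "encode_categories",
    "split_dataset",
    "Augmenter",
    "build_augmenter",
    "load_image_tree",
    "load_dicom_series",
    "convert_dicom_series",
    "write_manifest",
]

INPUT_SIZE = (128, 128, 3)
DEFAULT_SNR_THRESHOLD = 1.15

#: canonical names plus the spelled-out aliases used in run configurations
SCALING_TECHNIQUES = ("normalize", "standard", "minmax", "maxabs")
_SCALING_ALIASES = {
    "normalize": "normalize",
    "standard": "standard",
    "standardize": "standard",
    "min-max": "minmax",
    "minmax": "minmax",
    "max-abs": "maxabs",
    "maxabs": "maxabs",
}


@dataclass
class DatasetBundle:
    """Images with integer labels, class names, and per-image split tags."""

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    split: np.ndarray | None = None  # per-image tag in {train, validation, test}
    paths: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != self.labels.size:
            raise ValueError("images and labels length mismatch")
        K = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= K):
            raise ValueError("labels outside [0, K-1]")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, mask: np.ndarray) -> "DatasetBundle":
        idx = np.flatnonzero(mask)
        return DatasetBundle(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            split=None if self.split is None else self.split[idx],
            paths=None if self.paths is None else [self.paths[i] for i in idx],
        )

    def split_part(self, tag: str) -> "DatasetBundle":
        if self.split is None:
            raise ValueError("dataset has no split tags; call split_dataset first")
        return self.subset(self.split == tag)


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError(f"expected H x W x C image with C in (1, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def scale(image, technique: str) -> np.ndarray:
    """Apply one of the four pixel scaling techniques to a whole image.

    normalize: ``X / max(X)``; standardize: ``(X - mean) / std``;
    min-max: ``(X - min) / (max - min)``; max-abs: ``X / |max(X)|``.
    Degenerate inputs (zero denominator) raise ``ValueError``.
    """
    X = _as_image(image)
    key = _SCALING_ALIASES.get(technique.lower())
    if key is None:
        raise ValueError(f"unknown scaling technique {technique!r}")
    if key == "normalize":
        m = X.max()
        if m == 0:
            raise ValueError("normalize undefined: max(X) is zero")
        return X / m
    if key == "standard":
        sd = X.std()
        if sd == 0:
            raise ValueError("standardize undefined: zero standard deviation")
        return (X - X.mean()) / sd
    if key == "minmax":
        lo, hi = X.min(), X.max()
        if hi == lo:
            raise ValueError("min-max undefined: constant image")
        return (X - lo) / (hi - lo)
    m = abs(X.max())
    if m == 0:
        raise ValueError("max-abs undefined: |max(X)| is zero")
    return X / m


def resize_to_input(image, size: tuple[int, int, int] = INPUT_SIZE) -> np.ndarray:
    """Bicubic-resize to the network input size, replicating gray to RGB."""
    X = _as_image(image)
    H, W, C = size
    out = resize(
        X, (H, W, X.shape[2]), order=3, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    if X.shape[2] == 1 and C == 3:
        out = np.repeat(out, 3, axis=2)
    return out


def compute_snr(image) -> float:
    """Signal-to-noise ratio: mean pixel intensity over its standard deviation.

    A constant image has zero noise and is reported as ``+inf``.
    """
    X = _as_image(image)
    if X.max() == X.min():  # constant image: zero noise
        return float("inf")
    return float(X.mean() / X.std())


def clean_dataset(
    bundle: DatasetBundle, threshold: float = DEFAULT_SNR_THRESHOLD
) -> tuple[DatasetBundle, int]:
    """Drop images whose SNR is below ``threshold``; order is preserved."""
    snr = np.array([compute_snr(img) for img in bundle.images])
    keep = snr >= threshold
    kept = bundle.subset(keep)
    if len(kept) == 0 and len(bundle) > 0:
        warnings.warn("SNR cleaning removed every image", stacklevel=2)
    return kept, int((~keep).sum())


def encode_categories(class_names) -> dict[str, int]:
    """Map class names to consecutive integer codes in the given order."""
    names = list(class_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate class names")
    return {name: i for i, name in enumerate(names)}


def split_dataset(
    bundle: DatasetBundle,
    test_fraction: float = 0.15,
    validation_fraction: float = 0.10,
    seed: int | None = None,
) -> DatasetBundle:
    """Stratified train / validation / test split, tagged in place.

    ``test_fraction`` is the share of the whole dataset held out for testing
    (15% by default, leaving 85% for training and validation);
    ``validation_fraction`` is the share of that remaining training portion
    carved out for validation.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if not 0.0 <= validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in [0, 1)")
    n = len(bundle)
    idx = np.arange(n)
    counts = np.bincount(bundle.labels, minlength=bundle.n_classes)
    if np.any(counts < 2) or n * test_fraction < bundle.n_classes:
        raise ValueError("a class has too few images to stratify the split")
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=bundle.labels, random_state=seed
    )
    tags = np.full(n, "train", dtype=object)
    tags[test_idx] = "test"
    if validation_fraction > 0:
        tr_labels = bundle.labels[train_idx]
        if np.all(np.bincount(tr_labels, minlength=bundle.n_classes) >= 2):
            tr_idx, val_idx = train_test_split(
                train_idx,
                test_size=validation_fraction,
                stratify=tr_labels,
                random_state=None if seed is None else seed + 1,
            )
            tags[val_idx] = "validation"
    bundle.split = tags.astype(str)
    return bundle


# ---------------------------------------------------------------------------
# augmentation-based balancing
# ---------------------------------------------------------------------------


@dataclass
class Augmenter:
    """Seeded random geometric / photometric transform stream.

    Samples, per call: a rotation angle uniform in [-rotation, rotation]
    degrees, fractional width/height shifts, a shear, a zoom factor in
    [1 - zoom, 1 + zoom], Bernoulli(0.5) flips where enabled, and a
    multiplicative brightness factor uniform over ``brightness_range``.
    An identity-configured (or disabled) augmenter returns inputs unchanged.
    """

    rotation_deg: float = 0.0
    width_shift: float = 0.0
    height_shift: float = 0.0
    shear: float = 0.0
    zoom: float = 0.0
    horizontal_flip: bool = False
    vertical_flip: bool = False
    brightness_range: tuple[float, float] = (1.0, 1.0)
    enabled: bool = True
    seed: int | None = None
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.seed)

    def sample_params(self) -> dict[str, float]:
        r = self.rng
        return {
            "angle": float(r.uniform(-self.rotation_deg, self.rotation_deg)),
            "wshift": float(r.uniform(-self.width_shift, self.width_shift)),
            "hshift": float(r.uniform(-self.height_shift, self.height_shift)),
            "shear": float(r.uniform(-self.shear, self.shear)),
            "zoom": float(r.uniform(1.0 - self.zoom, 1.0 + self.zoom)),
            "hflip": bool(self.horizontal_flip and r.random() < 0.5),
            "vflip": bool(self.vertical_flip and r.random() < 0.5),
            "brightness": float(r.uniform(*self.brightness_range)),
        }

    def transform(self, image: np.ndarray) -> np.ndarray:
        X = _as_image(image)
        if not self.enabled:
            return X.copy()
        p = self.sample_params()
        geometric = (
            p["angle"] != 0.0 or p["wshift"] != 0.0 or p["hshift"] != 0.0
            or p["shear"] != 0.0 or p["zoom"] != 1.0
        )
        out = X
        if geometric:
            H, W = X.shape[:2]
            center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
            tform = (
                AffineTransform(translation=-center)
                + AffineTransform(
                    rotation=np.deg2rad(p["angle"]),
                    shear=p["shear"],
                    scale=(1.0 / p["zoom"], 1.0 / p["zoom"]),
                )
                + AffineTransform(
                    translation=center + [p["wshift"] * W, p["hshift"] * H]
                )
            )
            out = warp(out, tform.inverse, mode="edge", preserve_range=True)
        if p["hflip"]:
            out = out[:, ::-1]
        if p["vflip"]:
            out = out[::-1]
        if p["brightness"] != 1.0:
            out = out * p["brightness"]
        return np.ascontiguousarray(out, dtype=float)

    __call__ = transform

    def balanced_epoch(
        self, images: list[np.ndarray], labels: np.ndarray
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """One epoch's worth of class-balanced data.

        Minority classes are oversampled with augmented copies until every
        class matches the majority count; majority-class originals pass
        through the transform stream as well when augmentation is enabled.
        """
        labels = np.asarray(labels)
        classes, counts = np.unique(labels, return_counts=True)
        target = counts.max()
        out_images: list[np.ndarray] = []
        out_labels: list[int] = []
        for c in classes:
            members = np.flatnonzero(labels == c)
            extra = self.rng.choice(members, size=target - members.size, replace=True)
            for i in np.concatenate([members, extra]):
                img = images[int(i)]
                out_images.append(self.transform(img) if self.enabled else img)
                out_labels.append(int(c))
        return out_images, np.asarray(out_labels)


def build_augmenter(config: HyperparameterConfig, seed: int | None = None) -> Augmenter:
    """Build the balancing augmenter from a decoded configuration.

    With augmentation switched off in the configuration the returned
    transform is the identity (balancing still oversamples by repetition).
    """
    if not config.apply_augmentation:
        return Augmenter(enabled=False, seed=seed)
    return Augmenter(
        rotation_deg=config.rotation_deg,
        width_shift=config.width_shift,
        height_shift=config.height_shift,
        shear=config.shear,
        zoom=config.zoom,
        horizontal_flip=config.horizontal_flip,
        vertical_flip=config.vertical_flip,
        brightness_range=config.brightness_range,
        enabled=True,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# readers and manifests
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def load_image_tree(root, color_mode: str = "grayscale") -> DatasetBundle:
    """Read a class-per-folder image tree (PNG/JPEG) into a dataset bundle.

    Class names are the subdirectory names in sorted order; pixel values are
    scaled to [0, 1] floats.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} not found")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"{root} contains no class subdirectories")
    class_names = [d.name for d in class_dirs]
    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    for code, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            with Image.open(f) as im:
                im = im.convert("L" if color_mode == "grayscale" else "RGB")
                arr = np.asarray(im, dtype=float) / 255.0
            images.append(arr[:, :, np.newaxis] if arr.ndim == 2 else arr)
            labels.append(code)
            paths.append(str(f))
    return DatasetBundle(
        images=images, labels=np.asarray(labels, dtype=int),
        class_names=class_names, paths=paths,
    )


def load_dicom_series(directory) -> list[np.ndarray]:
    """Read every DICOM file in a directory into [0, 1]-scaled slice images."""
    import pydicom

    directory = Path(directory)
    slices: list[np.ndarray] = []
    for f in sorted(directory.iterdir()):
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f), force=True)
            arr = ds.pixel_array.astype(float)
        except Exception:
            continue
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        rng_ = arr.max() - arr.min()
        arr = (arr - arr.min()) / rng_ if rng_ > 0 else np.zeros_like(arr)
        slices.append(arr[:, :, np.newaxis])
    return slices


def convert_dicom_series(directory, out_dir) -> list[Path]:
    """Convert a DICOM series into 8-bit PNG slices; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, arr in enumerate(load_dicom_series(directory)):
        img = Image.fromarray((arr[:, :, 0] * 255).round().astype(np.uint8), mode="L")
        path = out_dir / f"slice_{i:04d}.png"
        img.save(path)
        written.append(path)
    return written


def write_manifest(bundle: DatasetBundle, path, threshold: float = DEFAULT_SNR_THRESHOLD) -> pd.DataFrame:
    """Write a per-image CSV manifest: path, class, SNR, kept flag."""
    snr = [compute_snr(img) for img in bundle.images]
    df = pd.DataFrame(
        {
            "path": bundle.paths if bundle.paths else [f"image_{i}" for i in range(len(bundle))],
            "class": [bundle.class_names[c] for c in bundle.labels],
            "snr": snr,
            "kept": [s >= threshold for s in snr],
        }
    )
    df.to_csv(path, index=False)
    return df
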