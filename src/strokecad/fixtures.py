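"""Synthetic image sets and feature tables with known class structure.

The public MRI collection this pipeline targets (178 axial T2-weighted
slices in six classes, sizes 25/25/24/54/26/24, 256x256) has no deposited
accession, so every downstream stage is exercised on synthetic data with
the same shape: six classes whose images differ in mean intensity, blob
count and texture frequency, and Gaussian feature clouds whose class means
sit at a controlled mutual separation.  Nothing here attempts radiological
realism; the generators exist to give the classifier a tunable degree of
class separability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InputError

#: class sizes of the six-class benchmark collection the pipeline targets
DEFAULT_CLASS_SIZES = (25, 25, 24, 54, 26, 24)
DEFAULT_IMAGE_SIZE = (256, 256)

N_CLASSES = 6


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic six-class image collection.

    Parameters
    ----------
    n_per_class:
        Number of images per class (six nonnegative integers).
    image_size:
        (rows, cols); both components must be >= 8.
    noise_sd:
        Standard deviation of additive pixel noise, in intensity units
        on the [0, 1] scale.
    class_contrast:
        Dimensionless scale on the class-specific mean-intensity shifts;
        larger values make classes easier to tell apart.
    seed:
        Seed for the single generator stream driving all randomness.
    """

    n_per_class: tuple[int, ...] = DEFAULT_CLASS_SIZES
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    noise_sd: float = 0.05
    class_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != N_CLASSES:
            raise InputError(
                f"n_per_class must list {N_CLASSES} classes, got {len(self.n_per_class)}"
            )
        if any(int(n) != n or n < 0 for n in self.n_per_class):
            raise InputError("n_per_class entries must be nonnegative integers")
        if len(self.image_size) != 2 or min(self.image_size) < 8:
            raise InputError("image_size components must be >= 8")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        object.__setattr__(self, "image_size", tuple(int(s) for s in self.image_size))


@dataclass
class LabeledImageSet:
    """Grayscale images with integer class labels in {0..5}."""

    images: list[np.ndarray]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise InputError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class LabeledFeatureTable:
    """A dense (n_samples, n_features) matrix plus integer labels."""

    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise InputError("feature matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise InputError("matrix rows and labels must have equal length")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("feature matrix contains non-finite values")

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


# per-class generative signature: (mean shift, blob count, texture frequency)
# chosen so every pair of classes differs in at least two of the three.
_CLASS_SIGNATURES = (
    (0.00, 2, 2.0),
    (0.08, 4, 3.0),
    (0.16, 6, 4.0),
    (-0.08, 3, 5.0),
    (0.24, 5, 6.0),
    (-0.16, 7, 7.0),
)


def _class_image(rng: np.random.Generator, cls: int, shape: tuple[int, int],
                 noise_sd: float, contrast: float) -> np.ndarray:
    rows, cols = shape
    shift, n_blobs, freq = _CLASS_SIGNATURES[cls]
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    yy /= rows
    xx /= cols
    img = np.full(shape, 0.45 + contrast * shift)
    # Gaussian blobs standing in for lesion-like foci
    sigma = 0.08
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.15, 0.85, size=2)
        amp = rng.uniform(0.15, 0.3)
        img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    # class-specific texture frequency
    phase = rng.uniform(0, 2 * np.pi)
    img += 0.05 * np.sin(2 * np.pi * freq * (xx + yy) + phase)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, 1.0)


def generate_images(spec: FixtureSpec) -> LabeledImageSet:
    """Generate the synthetic labeled image set described by ``spec``.

    Deterministic given ``spec.seed``: one generator stream drives blob
    placement, texture phase and pixel noise, so identical specs yield
    bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for cls, n in enumerate(spec.n_per_class):
        for _ in range(n):
            images.append(
                _class_image(rng, cls, spec.image_size, spec.noise_sd, spec.class_contrast)
            )
            labels.append(cls)
    return LabeledImageSet(images=images, labels=labels)


def _class_means(n_classes: int, n_features: int, separation: float) -> np.ndarray:
    """Class means at controlled mutual separation.

    With n_features >= n_classes the means are scaled one-hot axes, so
    every pair of classes is at Euclidean distance exactly `separation`.
    With fewer features they are equally spaced along the first axis
    (adjacent classes at distance `separation`).
    """
    means = np.zeros((n_classes, n_features))
    if n_features >= n_classes:
        for c in range(n_classes):
            means[c, c] = separation / np.sqrt(2.0)
    else:
        means[:, 0] = separation * np.arange(n_classes)
    return means


def generate_feature_table(
    n_per_class: Sequence[int],
    n_features: int,
    separation: float,
    seed: int,
) -> LabeledFeatureTable:
    """Class-conditional unit-variance Gaussian clouds.

    Each class is N(mu_c, I) with the mu_c mutually separated by
    ``separation`` (see :func:`_class_means`).  ``separation=0`` collapses
    all classes onto one cloud; at separation 6 two classes have
    closed-form Bayes error Phi(-3) ~ 0.13%.
    """
    if n_features < 1:
        raise InputError("n_features must be >= 1")
    if separation < 0:
        raise InputError("separation must be >= 0")
    if any(int(n) != n or n < 0 for n in n_per_class):
        raise InputError("n_per_class entries must be nonnegative integers")
    rng = np.random.default_rng(seed)
    means = _class_means(len(n_per_class), n_features, separation)
    rows, labels = [], []
    for cls, n in enumerate(n_per_class):
        rows.append(rng.normal(0.0, 1.0, size=(int(n), n_features)) + means[cls])
        labels.extend([cls] * int(n))
    matrix = np.vstack(rows) if rows else np.empty((0, n_features))
    return LabeledFeatureTable(matrix=matrix, labels=np.asarray(labels, dtype=int))


def save_images(image_set: LabeledImageSet, out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a ``labels.csv`` sidecar.

    Returns the path of the sidecar file (columns: filename, label).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = out / "labels.csv"
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, label) in enumerate(zip(image_set.images, image_set.labels)):
            name = f"img_{i:04d}.png"
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / name)
            writer.writerow([name, label])
    return sidecar


def load_images(labels_csv: str | Path) -> LabeledImageSet:
    """Load an image set written by :func:`save_images`."""
    sidecar = Path(labels_csv)
    base = sidecar.parent
    images, labels = [], []
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(base / row["filename"]).convert("L"), dtype=float)
            images.append(arr / 255.0)
            labels.append(int(row["label"]))
    return LabeledImageSet(images=images, labels=labels)


def save_feature_table(table: LabeledFeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV with a trailing ``label`` column."""
    path = Path(path)
    df = pd.DataFrame(table.matrix, columns=[f"f{i}" for i in range(table.matrix.shape[1])])
    df["label"] = table.labels
    df.to_csv(path, index=False)
    return path


def load_feature_table(path: str | Path) -> LabeledFeatureTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InputError(f"{path}: feature CSV must contain a 'label' column")
    labels = df.pop("label").to_numpy(dtype=int)
    return LabeledFeatureTable(matrix=df.to_numpy(dtype=float), labels=labels)
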