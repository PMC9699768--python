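"""Threshold-based preprocessing.

The pipeline binarizes each grayscale slice against a single global
threshold I — f(x,y) = 1 where g(x,y) >= I, else 0 — and by default uses
the resulting mask multiplicatively (background suppressed, foreground
intensities preserved) so downstream texture features still see intensity
structure.  A literal mode passes the binary mask itself downstream.

Threshold selection is pluggable: a fixed value, the global mean
intensity, or Otsu's between-class-variance maximizer (the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu

from .errors import InputError

THRESHOLD_METHODS = ("fixed", "mean", "otsu")


@dataclass
class BinaryMask:
    """A {0,1} pixel grid plus the threshold that produced it."""

    pixels: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isin(self.pixels, (0, 1)).all():
            raise InputError("mask values must be strictly binary")


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite values")
    return arr


def select_threshold(
    image: np.ndarray, method: str = "otsu", fixed_value: float | None = None
) -> float:
    """Choose the global threshold I for ``image``.

    ``mean`` returns the global mean intensity; ``otsu`` maximizes the
    between-class variance of the histogram; ``fixed`` returns
    ``fixed_value`` (which must lie within the image's intensity range).
    A constant image under ``otsu`` degenerates to the constant itself.
    """
    arr = _validate_image(image)
    if method == "fixed":
        if fixed_value is None:
            raise InputError("method='fixed' requires fixed_value")
        lo, hi = float(arr.min()), float(arr.max())
        if not (lo <= fixed_value <= hi):
            raise InputError(
                f"fixed_value {fixed_value} outside image intensity range [{lo}, {hi}]"
            )
        return float(fixed_value)
    if method == "mean":
        return float(arr.mean())
    if method == "otsu":
        if np.ptp(arr) == 0:  # constant image: no between-class variance to maximize
            return float(arr.flat[0])
        return float(threshold_otsu(arr))
    raise InputError(f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}")


def apply_threshold(image: np.ndarray, threshold: float) -> BinaryMask:
    """Binarize: output 1 where intensity >= threshold (boundary inclusive)."""
    arr = _validate_image(image)
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    return BinaryMask(pixels=(arr >= threshold).astype(np.uint8), threshold_used=float(threshold))


def masked_enhance(image: np.ndarray, mask: BinaryMask) -> np.ndarray:
    """Suppress background: image x mask, foreground intensities preserved."""
    arr = _validate_image(image)
    if arr.shape != mask.pixels.shape:
        raise InputError(f"shape mismatch: image {arr.shape} vs mask {mask.pixels.shape}")
    return arr * mask.pixels


def preprocess_image(
    image: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
    literal_binary: bool = False,
) -> np.ndarray:
    """Full preprocessing of one slice: select I, threshold, and either
    return the binary mask (``literal_binary``) or the masked image."""
    threshold = select_threshold(image, method=method, fixed_value=fixed_value)
    mask = apply_threshold(image, threshold)
    if literal_binary:
        return mask.pixels.astype(float)
    return masked_enhance(image, mask)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF, normalizing 8-bit values to [0, 1]."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def write_image(image: np.ndarray, path: str | Path) -> Path:
    arr = _validate_image(image)
    out = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="L").save(path)
    return Path(path)
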