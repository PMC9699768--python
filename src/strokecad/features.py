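"""Feature extraction behind a uniform extractor contract.

The classification stage consumes one fixed-length vector per image.  The
deterministic ``builtin_texture`` extractor — a normalized intensity
histogram, a gradient-orientation histogram and a grid of block means —
requires no trained weights and is what the test suite and default
pipeline run on.  Pretrained CNN backbones (MobileNet, EfficientNet-B3,
CapsNet) are optional plugins registered at runtime; requesting one that
is not installed raises a clean :class:`~strokecad.errors.CapabilityError`.
Per-extractor vectors are fused by (optionally standardized)
concatenation, the statistics being fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import CapabilityError, InputError

BUILTIN_EXTRACTOR = "builtin_texture"
KNOWN_BACKENDS = (BUILTIN_EXTRACTOR, "mobilenet", "efficientnet_b3", "capsnet")

N_HIST_BINS = 16
N_ORIENT_BINS = 8
BLOCK_GRID = 4  # 4x4 grid of block means

BUILTIN_DIM = N_HIST_BINS + N_ORIENT_BINS + BLOCK_GRID * BLOCK_GRID


@dataclass(frozen=True)
class ExtractorSpec:
    name: str = BUILTIN_EXTRACTOR
    output_dim: int = BUILTIN_DIM
    weights_source: str | None = None

    def __post_init__(self) -> None:
        if self.name not in KNOWN_BACKENDS:
            raise InputError(f"unknown extractor {self.name!r}; choose from {KNOWN_BACKENDS}")
        if self.output_dim < 1:
            raise InputError("output_dim must be >= 1")


@dataclass
class FeatureVector:
    values: np.ndarray
    extractor: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


# runtime plugin registry: name -> callable(image: 2-D array) -> 1-D array
_PLUGINS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_backend(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a feature-extraction plugin (e.g. a pretrained CNN tap)."""
    _PLUGINS[name] = fn


def builtin_texture(image: np.ndarray) -> np.ndarray:
    """Deterministic texture descriptor: intensity histogram (mass-
    normalized, 16 bins over [0,1]), gradient-orientation histogram
    (8 bins over [-pi, pi], weighted by gradient magnitude and normalized
    by total gradient energy; all-zero gradients yield a zero histogram),
    and 4x4 block means."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise InputError("builtin_texture expects a 2-D grayscale image")

    hist, _ = np.histogram(arr, bins=N_HIST_BINS, range=(0.0, 1.0))
    hist = hist / max(arr.size, 1)

    gy, gx = np.gradient(arr)
    mag = np.hypot(gx, gy)
    total = mag.sum()
    if total > 0:
        angle = np.arctan2(gy, gx)
        orient, _ = np.histogram(
            angle, bins=N_ORIENT_BINS, range=(-np.pi, np.pi), weights=mag
        )
        orient = orient / total
    else:
        orient = np.zeros(N_ORIENT_BINS)

    rows, cols = arr.shape
    r_edges = np.linspace(0, rows, BLOCK_GRID + 1).astype(int)
    c_edges = np.linspace(0, cols, BLOCK_GRID + 1).astype(int)
    blocks = np.array(
        [
            arr[r_edges[i] : r_edges[i + 1], c_edges[j] : c_edges[j + 1]].mean()
            for i in range(BLOCK_GRID)
            for j in range(BLOCK_GRID)
        ]
    )
    return np.concatenate([hist, orient, blocks])


def extract(image: np.ndarray, spec: ExtractorSpec | None = None) -> FeatureVector:
    """Extract one feature vector from a preprocessed image."""
    spec = spec or ExtractorSpec()
    if spec.name == BUILTIN_EXTRACTOR:
        return FeatureVector(values=builtin_texture(image), extractor=spec.name)
    fn = _PLUGINS.get(spec.name)
    if fn is None:
        raise CapabilityError(
            f"feature backend {spec.name!r} is not installed; register it with "
            f"strokecad.features.register_backend({spec.name!r}, fn) or use "
            f"{BUILTIN_EXTRACTOR!r}"
        )
    return FeatureVector(values=fn(image), extractor=spec.name)


@dataclass
class FusionStats:
    """Per-feature standardization statistics fitted on training data.

    Standard deviations below ``sd_floor`` are clamped to 1 so constant
    columns map to 0 instead of blowing up.
    """

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float = 1e-12

    @classmethod
    def fit(cls, fused_matrix: np.ndarray, sd_floor: float = 1e-12) -> "FusionStats":
        m = np.asarray(fused_matrix, dtype=float)
        mean = m.mean(axis=0)
        sd = m.std(axis=0, ddof=0)
        sd = np.where(sd <= sd_floor, 1.0, sd)
        return cls(mean=mean, sd=sd, sd_floor=sd_floor)

    def apply(self, vector: np.ndarray) -> np.ndarray:
        return (np.asarray(vector, dtype=float) - self.mean) / self.sd


def fuse(
    vectors: Sequence[FeatureVector],
    strategy: str = "concat",
    stats: FusionStats | None = None,
) -> FeatureVector:
    """Fuse per-extractor vectors for one image into a single vector.

    ``concat`` preserves per-extractor sublengths and ordering;
    ``concat_standardized`` additionally applies :class:`FusionStats`
    fitted on training data (required).
    """
    if not vectors:
        raise InputError("fuse requires at least one feature vector")
    values = np.concatenate([v.values for v in vectors])
    name = "+".join(v.extractor for v in vectors)
    if strategy == "concat":
        return FeatureVector(values=values, extractor=name)
    if strategy == "concat_standardized":
        if stats is None:
            raise InputError("concat_standardized requires fitted FusionStats")
        return FeatureVector(values=stats.apply(values), extractor=name)
    raise InputError(f"unknown fusion strategy {strategy!r}")


def extract_table(images: Sequence[np.ndarray], specs: Sequence[ExtractorSpec] | None = None,
                  strategy: str = "concat") -> np.ndarray:
    """Extract + fuse a whole image list into an (n, d) feature matrix.

    With ``concat_standardized`` the statistics are fitted on the given
    images themselves, so call this on training data (and reuse the stats
    via :class:`FusionStats` for held-out data if needed).
    """
    specs = list(specs) if specs else [ExtractorSpec()]
    raw = np.array([fuse([extract(img, s) for s in specs]).values for img in images])
    if strategy == "concat":
        return raw
    if strategy == "concat_standardized":
        return np.vstack([FusionStats.fit(raw).apply(row) for row in raw])
    raise InputError(f"unknown fusion strategy {strategy!r}")
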