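"""VOI biomarker vectors and first-order statistics.

Each modality (DKI / FLAIR) yields 54 biomarker candidates: for each of
the 9 feature channels (intensity + 8 MR8 max-responses), six summary
statistics over the in-VOI voxels.  The canonical index convention is
channel-major and 1-based:

* channel order: intensity, Gaussian, LoG, edge(3,1), edge(6,2),
  edge(12,4), bar(3,1), bar(6,2), bar(12,4)
* statistic order: mean, median, SD, kurtosis, p5, p95
* ``index = (channel - 1) * 6 + stat_position``

so e.g. index 7 is the mean of the Gaussian response and index 52 the
kurtosis of the bar(12,4) response.  SD uses the sample (n-1)
denominator, kurtosis is bias-corrected excess kurtosis (normal = 0),
skewness the adjusted Fisher-Pearson coefficient, and percentiles the
linear-interpolation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .dki import ScalarVolume
from .mr8 import CHANNEL_NAMES, ResponseChannels

__all__ = [
    "VoiMask",
    "BiomarkerVector",
    "FirstOrderStats",
    "STAT_NAMES",
    "N_BIOMARKERS",
    "extract_biomarkers",
    "biomarker_descriptor",
    "descriptor_to_index",
    "first_order_statistics",
    "concatenate_modalities",
]

STAT_NAMES = ("mean", "median", "SD", "kurtosis", "p5", "p95")
N_BIOMARKERS = len(CHANNEL_NAMES) * len(STAT_NAMES)  # 54

#: Minimum number of valid voxels for a usable VOI.
MIN_VOI_VOXELS = 10

_CHANNEL_DESCRIPTORS = (
    "intensity",
    "Gaussian filter response",
    "Laplacian of Gaussian filter response",
    "edge filter (scale [3,1]) response",
    "edge filter (scale [6,2]) response",
    "edge filter (scale [12,4]) response",
    "bar filter (scale [3,1]) response",
    "bar filter (scale [6,2]) response",
    "bar filter (scale [12,4]) response",
)


@dataclass
class VoiMask:
    """Binary tumor volume-of-interest on the image grid."""

    data: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.5)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if not np.any(self.data):
            raise ValueError("VOI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class BiomarkerVector:
    """The 54-element per-modality biomarker vector (1-based indexing)."""

    values: np.ndarray
    modality: str = "DKI"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BIOMARKERS,):
            raise ValueError(f"expected {N_BIOMARKERS} biomarkers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("biomarker values must be finite")

    def __getitem__(self, index: int) -> float:
        """Value at a 1-based biomarker index."""
        if not 1 <= index <= N_BIOMARKERS:
            raise IndexError(f"biomarker index {index} out of range 1..{N_BIOMARKERS}")
        return float(self.values[index - 1])

    def descriptor(self, index: int) -> str:
        return biomarker_descriptor(index)


@dataclass
class FirstOrderStats:
    """First-order descriptive statistics of MDK inside the VOI."""

    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    p5: float
    p95: float

    def as_feature_row(self) -> np.ndarray:
        """The six statistics used as SVM features (skewness excluded)."""
        return np.array([self.mean, self.median, self.sd, self.kurtosis, self.p5, self.p95])


def _channel_stats(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no valid voxels in channel")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if v.size > 3 and np.ptp(v) > 0:
        kurt = float(sps.kurtosis(v, fisher=True, bias=False))
    else:
        kurt = 0.0
    return np.array(
        [
            float(np.mean(v)),
            float(np.median(v)),
            sd,
            kurt,
            float(np.percentile(v, 5)),
            float(np.percentile(v, 95)),
        ]
    )


def extract_biomarkers(channels: ResponseChannels, mask, modality: str = "DKI") -> BiomarkerVector:
    """Reduce response channels to the canonical 54-element vector.

    NaN voxels (unfittable kurtosis fits) are dropped per channel; a VOI
    with fewer than 10 valid voxels raises ``ValueError``.
    """
    mask_arr = mask.data if isinstance(mask, VoiMask) else np.asarray(mask).astype(bool)
    if mask_arr.shape != channels.grid_shape:
        raise ValueError("mask and channels are on different grids")
    if not np.any(mask_arr):
        raise ValueError("VOI mask is empty")

    values = np.empty(N_BIOMARKERS)
    for c, name in enumerate(channels.names):
        in_voi = channels[name][mask_arr]
        n_valid = int(np.isfinite(in_voi).sum())
        if n_valid < MIN_VOI_VOXELS:
            raise ValueError(
                f"VOI has only {n_valid} valid voxels in channel '{name}' "
                f"(minimum {MIN_VOI_VOXELS})"
            )
        values[c * 6 : (c + 1) * 6] = _channel_stats(in_voi)
    return BiomarkerVector(values=values, modality=modality)


def biomarker_descriptor(index: int) -> str:
    """Human-readable descriptor of a 1-based biomarker index.

    >>> biomarker_descriptor(11)
    'p5 of Gaussian filter response'
    """
    if not 1 <= index <= N_BIOMARKERS:
        raise IndexError(f"biomarker index {index} out of range 1..{N_BIOMARKERS}")
    channel, stat = divmod(index - 1, 6)
    return f"{STAT_NAMES[stat]} of {_CHANNEL_DESCRIPTORS[channel]}"


def descriptor_to_index(descriptor: str) -> int:
    """Inverse of :func:`biomarker_descriptor`."""
    for i in range(1, N_BIOMARKERS + 1):
        if biomarker_descriptor(i) == descriptor:
            return i
    raise ValueError(f"unknown biomarker descriptor: {descriptor!r}")


def first_order_statistics(mdk, mask) -> FirstOrderStats:
    """Seven descriptive statistics of the MDK map inside the VOI."""
    data = mdk.data if isinstance(mdk, ScalarVolume) else np.asarray(mdk, dtype=float)
    mask_arr = mask.data if isinstance(mask, VoiMask) else np.asarray(mask).astype(bool)
    if mask_arr.shape != data.shape:
        raise ValueError("mask and volume are on different grids")
    if not np.any(mask_arr):
        raise ValueError("VOI mask is empty")
    v = data[mask_arr]
    v = v[np.isfinite(v)]
    if v.size < MIN_VOI_VOXELS:
        raise ValueError(f"VOI has only {v.size} valid voxels (minimum {MIN_VOI_VOXELS})")
    skew = float(sps.skew(v, bias=False)) if np.ptp(v) > 0 else 0.0
    m = _channel_stats(v)
    return FirstOrderStats(
        mean=m[0], median=m[1], sd=m[2], skewness=skew, kurtosis=m[3], p5=m[4], p95=m[5]
    )


def concatenate_modalities(dki: BiomarkerVector, flair: BiomarkerVector) -> np.ndarray:
    """Concatenate DKI then FLAIR biomarkers into a 108-element vector."""
    if dki.modality == flair.modality:
        raise ValueError("expected two distinct modalities")
    return np.concatenate([dki.values, flair.values])
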