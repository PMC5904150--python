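"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end:

* :func:`simulate_dwi_signal` — per-voxel diffusion signal decays from the
  kurtosis model, with Rician magnitude noise, at a configurable b-value
  scheme (default: the six-shell 0–2800 s/mm^2, 30-direction scheme).
* :func:`generate_phantom_cohort` — two-class cohorts of 3D texture
  phantoms ("MDK-like" and "FLAIR-like" scalar volumes with spherical
  tumor VOIs).  Textures are stationary Gaussian random fields: white
  noise convolved with an isotropic Gaussian whose width is the class
  correlation length.
* :func:`generate_tabular_features` — feature matrices with planted
  informative columns, for feature-selection recovery experiments.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dki import DwiSeries, ScalarVolume

__all__ = [
    "SignalGroundTruth",
    "PhantomSpec",
    "SyntheticCohort",
    "DEFAULT_B_VALUES",
    "kurtosis_signal",
    "fibonacci_directions",
    "simulate_dwi_signal",
    "generate_phantom_cohort",
    "generate_tabular_features",
]

#: Six-shell acquisition scheme (s/mm^2) used throughout.
DEFAULT_B_VALUES = (0.0, 500.0, 1000.0, 1500.0, 2000.0, 2800.0)


@dataclass(frozen=True)
class SignalGroundTruth:
    """True parameters behind a simulated diffusion decay.

    ``s0`` baseline signal (a.u., > 0); ``d_app`` apparent diffusivity
    (mm^2/s, > 0); ``k_app`` apparent kurtosis (dimensionless, >= 0);
    ``noise_sigma`` Rician noise scale in the units of ``s0``.
    """

    s0: float = 1000.0
    d_app: float = 1.0e-3
    k_app: float = 0.8
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.d_app <= 0:
            raise ValueError("d_app must be positive")
        if self.k_app < 0:
            raise ValueError("k_app must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def kurtosis_signal(s0, d, k, b):
    """Noiseless kurtosis-model signal S0*exp(-b*D + (1/6)*b^2*D^2*K)."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * d + (b * b * d * d * k) / 6.0)


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` approximately uniform unit vectors on the sphere."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def simulate_dwi_signal(
    truth: SignalGroundTruth,
    b_values=DEFAULT_B_VALUES,
    n_directions: int = 30,
    seed: int = 0,
    n_voxels: int = 1,
) -> DwiSeries:
    """Simulate a DWI series from known kurtosis-model parameters.

    For ``noise_sigma == 0`` the signal is exactly the kurtosis-model
    decay at every b; otherwise Rician magnitude noise is applied:
    ``sqrt((S + e1)^2 + e2^2)`` with independent Gaussian(0, sigma) e1, e2.

    Returns a :class:`~dkitex.dki.DwiSeries` with signal shape
    ``(n_voxels, n_b, n_directions)``.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise ValueError("b_values must be non-empty")
    if np.any(b < 0):
        raise ValueError("b_values must be non-negative")
    if not np.any(b == 0):
        raise ValueError("b_values must include b=0")
    clean = kurtosis_signal(truth.s0, truth.d_app, truth.k_app, b)
    sig = np.broadcast_to(clean[None, :, None], (n_voxels, b.size, n_directions)).copy()
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, truth.noise_sigma, sig.shape)
        e2 = rng.normal(0.0, truth.noise_sigma, sig.shape)
        sig = np.sqrt((sig + e1) ** 2 + e2**2)
    return DwiSeries(signal=sig, b_values=b, directions=fibonacci_directions(n_directions))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-class texture-phantom cohort.

    Defaults emulate the cohort structure this pipeline targets: a
    128x128 in-plane grid at 2.5 mm slices, 26 vs 11 subjects, and
    class-conditional mean MDK inside the VOI of ~522 vs ~637 a.u.
    (class 0 = the low-MDK class).  ``class_texture_scale`` is the
    correlation length (in voxels) of the Gaussian random field inside
    the VOI.  ``flair_class_means`` defaults to identical values so the
    FLAIR-like channel carries no class signal unless requested.
    """

    grid_shape: tuple = (128, 128, 12)
    voxel_size: tuple = (1.95, 1.95, 2.5)
    n_subjects_per_class: tuple = (26, 11)
    class_mean_mdk: tuple = (521.8, 637.4)
    class_texture_scale: tuple = (2.0, 2.0)
    voi_radius: float = 10.0
    voi_radius_jitter: float = 2.0
    subject_mean_sd: float = 40.0
    field_sd: float = 60.0
    background_mean: float = 350.0
    flair_class_means: tuple = (500.0, 500.0)
    flair_texture_scale: tuple = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects_per_class) < 2:
            raise ValueError("each class needs >= 2 subjects")
        if min(self.class_texture_scale) <= 0 or min(self.flair_texture_scale) <= 0:
            raise ValueError("correlation lengths must be positive")
        max_r = self.voi_radius + self.voi_radius_jitter
        if 2 * max_r >= min(self.grid_shape[:2]) or 2 * max_r >= self.grid_shape[2] * 4:
            if 2 * max_r >= min(self.grid_shape):
                raise ValueError("VOI does not fit inside the grid")


@dataclass
class SyntheticCohort:
    """A generated cohort: per-subject volumes, masks, labels, and truth."""

    mdk_volumes: list
    flair_volumes: list
    masks: list
    labels: np.ndarray
    spec: PhantomSpec
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.labels))]
        if not (len(self.mdk_volumes) == len(self.flair_volumes) == len(self.masks) == len(self.labels)):
            raise ValueError("inconsistent cohort lengths")
        for m in self.masks:
            if not np.any(m):
                raise ValueError("empty VOI mask")

    def __len__(self):
        return len(self.labels)


def _grf(rng, shape, scale, mean, sd):
    """Stationary Gaussian random field: smoothed white noise rescaled to
    the requested pointwise mean and SD."""
    white = rng.standard_normal(shape)
    sm = gaussian_filter(white, sigma=scale, mode="reflect")
    s = sm.std()
    if s > 0:
        sm = sm / s
    return mean + sd * sm


def _sphere_mask(shape, center, radius):
    zz = np.indices(shape).astype(float)
    d2 = sum((zz[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius * radius


def generate_phantom_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """Generate a two-class cohort of texture phantoms.

    Each subject gets an MDK-like and a FLAIR-like scalar volume (both
    Gaussian random fields) and a spherical VOI mask.  Inside the VOI the
    MDK-like field has the subject's class mean (plus a subject-level
    offset) and the class correlation length; outside it sits at the
    background mean.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_subjects_per_class
    labels = np.array([0] * n0 + [1] * n1, dtype=int)
    mdk_volumes, flair_volumes, masks = [], [], []
    shape = tuple(int(s) for s in spec.grid_shape)
    center0 = np.array(shape, dtype=float) / 2.0

    for lab in labels:
        radius = spec.voi_radius + rng.uniform(-spec.voi_radius_jitter, spec.voi_radius_jitter)
        radius = max(radius, 2.0)
        jitter = rng.uniform(-2.0, 2.0, size=3)
        center = np.clip(center0 + jitter, radius + 1, np.array(shape) - radius - 1)
        # keep the sphere inside thin-slab grids
        center[2] = np.clip(center[2], 0, shape[2] - 1)
        eff_r = min(radius, (shape[2] - 1) / 2.0)
        mask = _sphere_mask(shape, center, eff_r)
        if not np.any(mask):
            mask = _sphere_mask(shape, center0, 2.0)

        subj_mean = spec.class_mean_mdk[lab] + rng.normal(0.0, spec.subject_mean_sd)
        mdk = _grf(rng, shape, spec.class_texture_scale[lab], spec.background_mean, spec.field_sd)
        tumor = _grf(rng, shape, spec.class_texture_scale[lab], subj_mean, spec.field_sd)
        mdk[mask] = tumor[mask]

        flair_mean = spec.flair_class_means[lab] + rng.normal(0.0, spec.subject_mean_sd)
        flair = _grf(rng, shape, spec.flair_texture_scale[lab], spec.background_mean, spec.field_sd)
        flair_t = _grf(rng, shape, spec.flair_texture_scale[lab], flair_mean, spec.field_sd)
        flair[mask] = flair_t[mask]

        mdk_volumes.append(ScalarVolume(mdk, voxel_size=spec.voxel_size, modality="MDK"))
        flair_volumes.append(ScalarVolume(flair, voxel_size=spec.voxel_size, modality="FLAIR"))
        masks.append(mask)

    return SyntheticCohort(
        mdk_volumes=mdk_volumes,
        flair_volumes=flair_volumes,
        masks=masks,
        labels=labels,
        spec=spec,
    )


def generate_tabular_features(
    n_samples: int,
    n_features: int,
    informative_idx=(),
    effect_size: float = 2.0,
    class_ratio=(26, 11),
    seed: int = 0,
):
    """Feature matrix with planted informative columns.

    ``informative_idx`` uses the 1-based biomarker index convention.
    Informative columns get a class-1 mean shift of ``effect_size`` SDs;
    all other columns are pure standard-normal noise.  ``class_ratio``
    fixes the exact per-class counts (scaled to ``n_samples`` if their
    sum differs).

    Returns
    -------
    X : ndarray (n_samples, n_features)
    y : ndarray (n_samples,) of {0, 1}
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    informative_idx = sorted(set(int(i) for i in informative_idx))
    if informative_idx and (informative_idx[0] < 1 or informative_idx[-1] > n_features):
        raise ValueError("informative_idx must lie in 1..n_features")

    r0, r1 = class_ratio
    if r0 + r1 == n_samples:
        n1 = r1
    else:
        n1 = max(1, round(n_samples * r1 / (r0 + r1)))
    n0 = n_samples - n1
    rng = np.random.default_rng(seed)
    y = np.array([0] * n0 + [1] * n1, dtype=int)
    rng.shuffle(y)
    X = rng.standard_normal((n_samples, n_features))
    for idx in informative_idx:
        X[y == 1, idx - 1] += effect_size
    return X, y
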