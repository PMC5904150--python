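"""Per-voxel diffusional kurtosis model fitting and MDK parametric maps.

The signal model for an isotropic (per-direction scalar) kurtosis fit is

    S(b) = S0 * exp(-b * D + (1/6) * b^2 * D^2 * K)

with apparent diffusivity ``D`` (mm^2/s) and apparent kurtosis ``K``
(dimensionless).  Taking logarithms makes the model linear in the
parameters ``(ln S0, D, beta2)`` with ``beta2 = D^2 K / 6``, so each
voxel/direction is fitted by ordinary least squares on the log-signal and
``K`` is recovered as ``6 * beta2 / D^2``.  The mean diffusional kurtosis
(MDK) map averages the per-direction kurtosis estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DwiSeries",
    "KurtosisVoxelFit",
    "ScalarVolume",
    "fit_kurtosis_voxel",
    "fit_kurtosis_directions",
    "compute_mdk_map",
    "D_MIN",
    "K_MAX",
]

#: Lower bound for the projected diffusivity estimate (mm^2/s).
D_MIN = 1e-6
#: Upper bound for the projected kurtosis estimate (plausible brain range).
K_MAX = 3.0


@dataclass
class DwiSeries:
    """A diffusion-weighted series on a voxel grid.

    Parameters
    ----------
    signal : ndarray, shape (..., n_b, n_dir)
        Non-negative magnitude signal; the leading axes index voxels
        (any shape, typically 3D), followed by b-value and direction axes.
    b_values : ndarray, shape (n_b,)
        Diffusion weightings in s/mm^2, strictly increasing, first one 0.
    directions : ndarray, shape (n_dir, 3)
        Unit gradient vectors.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    """

    signal: np.ndarray
    b_values: np.ndarray
    directions: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.5)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.b_values.ndim != 1 or self.b_values.size < 1:
            raise ValueError("b_values must be a non-empty 1D array")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if self.b_values[0] != 0:
            raise ValueError("b_values must start at b=0")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if self.signal.shape[-2] != self.b_values.size:
            raise ValueError("signal b-axis does not match b_values")
        if self.signal.shape[-1] != self.directions.shape[0]:
            raise ValueError("signal direction-axis does not match directions")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions must be unit vectors")

    @property
    def grid_shape(self) -> tuple:
        return self.signal.shape[:-2]


@dataclass
class KurtosisVoxelFit:
    """Result of per-direction kurtosis fits for one voxel."""

    s0_hat: float
    d_hat: np.ndarray  # (n_dir,) apparent diffusivity per direction, mm^2/s
    k_hat: np.ndarray  # (n_dir,) apparent kurtosis per direction
    rss: np.ndarray  # (n_dir,) residual sum of squares of the log fit
    valid: np.ndarray = field(default=None)  # (n_dir,) bool

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones_like(np.atleast_1d(self.k_hat), dtype=bool)

    @property
    def mdk(self) -> float:
        """Mean kurtosis over valid directions (NaN if none valid)."""
        if not np.any(self.valid):
            return float("nan")
        return float(np.mean(np.atleast_1d(self.k_hat)[self.valid]))


@dataclass
class ScalarVolume:
    """A 3D scalar map (e.g. an MDK or FLAIR-like volume)."""

    data: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.5)
    modality: str = "MDK"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarVolume expects a 3D array")


def _design_matrix(b_values: np.ndarray) -> np.ndarray:
    b = np.asarray(b_values, dtype=float)
    return np.column_stack([np.ones_like(b), -b, b * b])


def _solve_log_fit(log_signal: np.ndarray, design: np.ndarray):
    """Least-squares solve of the log-linear kurtosis model.

    ``log_signal`` has shape (n_b, m) for m independent fits; returns
    (s0, d, k, rss) arrays of length m with the positivity/box projections
    applied (D >= D_MIN, K in [0, K_MAX]).
    """
    theta, _, _, _ = np.linalg.lstsq(design, log_signal, rcond=None)
    resid = log_signal - design @ theta
    rss = np.sum(resid * resid, axis=0)
    ln_s0, d, beta2 = theta
    d = np.maximum(d, D_MIN)
    k = np.clip(6.0 * beta2 / (d * d), 0.0, K_MAX)
    return np.exp(ln_s0), d, k, rss


def fit_kurtosis_voxel(signal, b_values) -> KurtosisVoxelFit:
    """Fit the kurtosis model for a single voxel.

    Parameters
    ----------
    signal : ndarray, shape (n_b,) or (n_b, n_dir)
        Positive magnitude signal per b-value (and optionally direction).
    b_values : ndarray, shape (n_b,)
        Diffusion weightings, at least 3 distinct values including 0.

    Returns
    -------
    KurtosisVoxelFit
        Estimates per direction.  Directions containing non-positive
        signal are flagged invalid (log undefined) and carry NaN.

    Raises
    ------
    ValueError
        If fewer than 3 distinct b-values are given (rank-deficient
        design) or b=0 is missing.
    """
    b = np.asarray(b_values, dtype=float)
    if np.unique(b).size < 3:
        raise ValueError("kurtosis fit needs >= 3 distinct b-values")
    if not np.any(b == 0):
        raise ValueError("b_values must include b=0")
    sig = np.atleast_2d(np.asarray(signal, dtype=float).T).T  # (n_b, n_dir)
    if sig.shape[0] != b.size:
        raise ValueError("signal length does not match b_values")

    n_dir = sig.shape[1]
    valid = np.all(sig > 0, axis=0)
    d = np.full(n_dir, np.nan)
    k = np.full(n_dir, np.nan)
    rss = np.full(n_dir, np.nan)
    s0 = np.nan
    if np.any(valid):
        design = _design_matrix(b)
        s0s, dv, kv, rs = _solve_log_fit(np.log(sig[:, valid]), design)
        d[valid], k[valid], rss[valid] = dv, kv, rs
        s0 = float(np.mean(s0s))
    return KurtosisVoxelFit(s0_hat=s0, d_hat=d, k_hat=k, rss=rss, valid=valid)


def fit_kurtosis_directions(signal: np.ndarray, b_values: np.ndarray):
    """Vectorised per-direction kurtosis fit for many voxels at once.

    ``signal`` has shape (n_vox, n_b, n_dir); returns (d, k, rss, valid)
    arrays of shape (n_vox, n_dir).  Fits with any non-positive sample are
    marked invalid and returned as NaN.
    """
    sig = np.asarray(signal, dtype=float)
    n_vox, n_b, n_dir = sig.shape
    design = _design_matrix(b_values)
    flat = sig.transpose(1, 0, 2).reshape(n_b, n_vox * n_dir)
    valid = np.all(flat > 0, axis=0)
    d = np.full(n_vox * n_dir, np.nan)
    k = np.full(n_vox * n_dir, np.nan)
    rss = np.full(n_vox * n_dir, np.nan)
    if np.any(valid):
        _, dv, kv, rs = _solve_log_fit(np.log(flat[:, valid]), design)
        d[valid], k[valid], rss[valid] = dv, kv, rs
    shape = (n_vox, n_dir)
    return d.reshape(shape), k.reshape(shape), rss.reshape(shape), valid.reshape(shape)


def compute_mdk_map(dwi: DwiSeries, mask=None) -> ScalarVolume:
    """Compute the mean diffusional kurtosis (MDK) map.

    Each in-mask voxel is fitted independently per gradient direction and
    MDK is the arithmetic mean of the per-direction kurtosis estimates.
    Voxels with no valid direction (non-positive signal) are NaN.

    Parameters
    ----------
    dwi : DwiSeries
    mask : ndarray of bool, optional
        Voxels to fit; outside voxels are left NaN.  Must match the DWI
        grid.

    Returns
    -------
    ScalarVolume with modality "MDK".
    """
    grid = dwi.grid_shape
    if mask is None:
        mask_flat = np.ones(int(np.prod(grid)), dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid:
            raise ValueError(f"mask shape {mask.shape} != DWI grid {grid}")
        mask_flat = mask.reshape(-1)

    sig = dwi.signal.reshape(-1, dwi.b_values.size, dwi.directions.shape[0])
    mdk = np.full(sig.shape[0], np.nan)
    if np.any(mask_flat):
        _, k, _, valid = fit_kurtosis_directions(sig[mask_flat], dwi.b_values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mdk[mask_flat] = np.nanmean(np.where(valid, k, np.nan), axis=1)
        n_bad = int(np.sum(np.isnan(mdk[mask_flat])))
        if n_bad:
            warnings.warn(f"{n_bad} in-mask voxels had no valid direction fit")
    data = mdk.reshape(grid) if len(grid) else mdk.reshape(1, 1, 1)
    if data.ndim != 3:
        data = data.reshape(grid + (1,) * (3 - len(grid)))
    return ScalarVolume(data=data, voxel_size=dwi.voxel_size, modality="MDK")
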