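"""Volume I/O, masking, geometry and time-series hygiene.

All volumes handled by the package live in a canonical RAS orientation
(+x = subject left→right). Reading a NIfTI file reorients to canonical
axes by explicit axis permutation/reversal — never by resampling — and
no operation in this module silently interpolates between geometries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage, stats

from .errors import GeometryError, InvalidConfigError

#: FWHM of a Gaussian divided by its standard deviation.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape + affine of a 3D volume (canonical RAS orientation)."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def matches(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def isotropic_geometry(shape, voxel_size_mm: float = 2.0) -> VolumeGeometry:
    """RAS geometry with isotropic voxels and origin at the corner voxel."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return VolumeGeometry(tuple(shape), aff)


@dataclass(frozen=True)
class BrainMask:
    """Boolean in-brain mask with a stable lexicographic voxel ordering."""

    geometry: VolumeGeometry
    include: np.ndarray

    def __post_init__(self):
        inc = np.asarray(self.include, dtype=bool)
        if inc.shape != self.geometry.shape:
            raise GeometryError("mask array shape does not match geometry")
        if inc.sum() < 1:
            raise InvalidConfigError("mask must contain at least one voxel")
        inc.setflags(write=False)
        object.__setattr__(self, "include", inc)

    @property
    def V(self) -> int:
        return int(self.include.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of in-mask voxels, lexicographic by (i,j,k)."""
        return np.flatnonzero(self.include.ravel(order="C"))

    def voxel_coords(self) -> np.ndarray:
        """(V, 3) integer voxel coordinates of in-mask voxels."""
        return np.argwhere(self.include)

    def world_coords(self) -> np.ndarray:
        """(V, 3) world (mm) coordinates of in-mask voxel centers."""
        ijk = self.voxel_coords()
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.geometry.affine @ hom.T).T[:, :3]

    def intersect(self, other: "BrainMask") -> "BrainMask":
        if not self.geometry.matches(other.geometry):
            raise GeometryError("cannot intersect masks with different geometry")
        return BrainMask(self.geometry, self.include & other.include)


@dataclass(frozen=True)
class ConditionLabel:
    """Label of one activation image within the 3×2×2 design."""

    subject: int
    modality: str  # "somatic" | "vicarious"
    level: int  # 1 = low … n = high (rank within the level ladder)
    site: str  # "UL" | "LL"


@dataclass
class ActivationImage:
    """One beta/contrast map vectorized over a mask."""

    mask: BrainMask
    values: np.ndarray
    label: Optional[ConditionLabel] = None
    rating: Optional[float] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape[0] != self.mask.V:
            raise GeometryError(
                f"values length {v.shape} does not match mask V={self.mask.V}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("activation values must be finite")
        self.values = v


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> tuple:
    """Read a NIfTI volume, reorienting to canonical RAS.

    Returns ``(data, geometry)``. Reorientation is a pure axis
    permutation/reversal (nibabel's closest-canonical transform);
    voxel values are never interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=float)
    return data, VolumeGeometry(data.shape[:3], img.affine)


def write_volume(values: np.ndarray, geometry: VolumeGeometry, path) -> None:
    """Write a 3D (or 4D) array as NIfTI-1 with the given affine."""
    values = np.asarray(values)
    if tuple(values.shape[:3]) != geometry.shape:
        raise GeometryError("volume shape does not match geometry")
    img = nib.Nifti1Image(values.astype(np.float32), geometry.affine)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    data, geom = read_volume(path)
    return BrainMask(geom, data > 0.5)


def write_mask(mask: BrainMask, path) -> None:
    write_volume(mask.include.astype(np.float32), mask.geometry, path)


# ---------------------------------------------------------------------------
# Masking / vectorization


def vectorize(volume: np.ndarray, mask: BrainMask,
              label: Optional[ConditionLabel] = None,
              rating: Optional[float] = None) -> ActivationImage:
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.geometry.shape:
        raise GeometryError(
            f"volume shape {volume.shape} != mask geometry {mask.geometry.shape}"
        )
    return ActivationImage(mask, volume[mask.include], label=label, rating=rating)


def unvectorize(image_or_values, mask: Optional[BrainMask] = None) -> np.ndarray:
    """Scatter a masked vector back into a full volume (zeros outside)."""
    if isinstance(image_or_values, ActivationImage):
        mask = image_or_values.mask
        vec = image_or_values.values
    else:
        if mask is None:
            raise ValueError("mask required when passing a bare vector")
        vec = np.asarray(image_or_values, dtype=float)
        if vec.shape != (mask.V,):
            raise GeometryError("vector length does not match mask V")
    out = np.zeros(mask.geometry.shape, dtype=float)
    out[mask.include] = vec
    return out


# ---------------------------------------------------------------------------
# Geometric operations


def flip_lr_volume(volume: np.ndarray) -> np.ndarray:
    """Mirror a canonical-RAS volume across the mid-sagittal plane.

    Voxel (i, j, k) maps to (nx-1-i, j, k)."""
    return np.asarray(volume)[::-1, :, :].copy()


def flip_lr_mask(mask: BrainMask) -> BrainMask:
    return BrainMask(mask.geometry, flip_lr_volume(mask.include))


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: Sequence[float] | float = 2.0) -> np.ndarray:
    """Gaussian smoothing with FWHM in mm and reflective boundaries.

    ``fwhm_mm = 0`` is the identity. The kernel is normalized, so a
    constant volume (and, up to boundary effects, the volume mean) is
    preserved.
    """
    if fwhm_mm < 0:
        raise InvalidConfigError("fwhm_mm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm / FWHM_PER_SIGMA) / vs
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


# ---------------------------------------------------------------------------
# Spike / outlier detection


@dataclass
class SpikeReport:
    """Per-volume Mahalanobis distances and flagged outlier volumes."""

    distances: np.ndarray  # squared Mahalanobis distance per volume
    threshold: float
    flagged: np.ndarray  # indices of flagged volumes
    alpha: float
    df: int
    shrinkage_used: bool = False

    def to_frame(self):
        import pandas as pd

        flagged = np.zeros(len(self.distances), dtype=bool)
        flagged[self.flagged] = True
        return pd.DataFrame(
            {"volume": np.arange(len(self.distances)),
             "d2": self.distances, "flagged": flagged}
        )


def spike_features(series: np.ndarray, slice_axis: int = 2) -> np.ndarray:
    """Per-volume feature vector: slice-wise means ++ slice-wise SDs.

    ``series`` is 4D with time last. Slices are taken along ``slice_axis``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise InvalidConfigError("series must be 4D (x, y, z, t)")
    t_axis = 3
    n_t = series.shape[t_axis]
    # move slice axis and time to front for reduction
    arr = np.moveaxis(series, (slice_axis, t_axis), (0, 1))
    n_slices = arr.shape[0]
    flat = arr.reshape(n_slices, n_t, -1)
    means = flat.mean(axis=2)  # (n_slices, T)
    sds = flat.std(axis=2, ddof=1)
    return np.concatenate([means, sds], axis=0).T  # (T, 2*n_slices)


def detect_spikes(series: np.ndarray, alpha: float = 0.05,
                  slice_axis: int = 2) -> SpikeReport:
    """Flag global-outlier volumes by Mahalanobis distance.

    The feature for each volume is the concatenation of slice-wise means
    and slice-wise standard deviations. Squared Mahalanobis distances to
    the time-wise mean are referred to a χ²(2·n_slices) quantile at a
    Bonferroni-corrected ``alpha`` (corrected across volumes). When the
    number of volumes is below twice the feature count the covariance is
    estimated with Ledoit-Wolf shrinkage toward the diagonal.
    """
    feats = spike_features(series, slice_axis=slice_axis)
    n_t, p = feats.shape
    if n_t < 3:
        raise InvalidConfigError("need at least 3 volumes for spike detection")
    center = feats.mean(axis=0)
    dev = feats - center
    shrink = n_t < 2 * p
    if shrink:
        from sklearn.covariance import LedoitWolf

        warnings.warn(
            "few volumes relative to features; using Ledoit-Wolf "
            "covariance shrinkage for spike detection",
            stacklevel=2,
        )
        cov = LedoitWolf(assume_centered=False).fit(feats).covariance_
    else:
        cov = np.cov(feats, rowvar=False, ddof=1)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
    d2 = np.einsum("ij,jk,ik->i", dev, prec, dev)
    threshold = stats.chi2.ppf(1.0 - alpha / n_t, df=p)
    flagged = np.flatnonzero(d2 > threshold)
    return SpikeReport(distances=d2, threshold=float(threshold),
                       flagged=flagged, alpha=alpha, df=p,
                       shrinkage_used=shrink)


# ---------------------------------------------------------------------------
# High-pass filtering


def dct_drift_basis(n_scans: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (periods >= cutoff), without the constant.

    Columns are the unit-norm DCT-II basis functions
    ``cos(pi*(2t+1)*k / (2N))`` for k = 1..K with K = floor(2*N*tr/cutoff).
    """
    n_funcs = int(np.floor(2.0 * n_scans * tr_s / cutoff_s))
    t = np.arange(n_scans)
    cols = []
    for k in range(1, n_funcs + 1):
        c = np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_scans))
        cols.append(c * np.sqrt(2.0 / n_scans))
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def dct_highpass(series: np.ndarray, cutoff_s: float, tr_s: float,
                 time_axis: int = 0) -> np.ndarray:
    """Remove slow drifts by regressing out a DCT basis (plus the mean).

    The residual is orthogonal to every removed basis function. Raises if
    the cutoff is not above twice the TR (nothing slower than Nyquist to
    remove).
    """
    if cutoff_s <= 2.0 * tr_s:
        raise InvalidConfigError("cutoff_s must exceed 2*tr_s")
    series = np.asarray(series, dtype=float)
    y = np.moveaxis(series, time_axis, 0)
    shp = y.shape
    y2 = y.reshape(shp[0], -1)
    basis = dct_drift_basis(shp[0], tr_s, cutoff_s)
    # orthonormal columns + mean removal: project out span{1, basis}
    resid = y2 - y2.mean(axis=0, keepdims=True)
    if basis.shape[1]:
        resid = resid - basis @ (basis.T @ resid)
    return np.moveaxis(resid.reshape(shp), 0, time_axis)
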