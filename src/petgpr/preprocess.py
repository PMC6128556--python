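"""Volume preprocessing: smoothing, downsampling, masking, scaling, age removal.

The fixed pipeline order mirrors standard voxel-based FDG-PET analysis:

    smooth -> downsample -> vectorize (mask) -> global-mean scale
           -> voxelwise age residualization

Each subject's volume ends up as one row of a :class:`FeatureMatrix`; the
``stage`` tag ("raw" -> "scaled" -> "residualized") gates the order so
stages cannot silently run out of sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MetabolicVolume",
    "FeatureMatrix",
    "AgeResidualizer",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "downsample_by_two",
    "downsample_mask",
    "vectorize",
    "devectorize",
    "global_mean_scale",
    "residualize_age",
    "scale_features",
    "residualize_features",
    "preprocess_volumes",
]

STAGES = ("raw", "scaled", "residualized")

# FWHM = sigma * 2*sqrt(2*ln 2)
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class MetabolicVolume:
    """One subject's 3-D uptake grid with its voxel geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


@dataclass
class FeatureMatrix:
    """Subjects x in-mask voxels, with the mapping back to grid coordinates.

    ``voxel_index[j]`` is the (i, j, k) coordinate of column j in the
    (possibly downsampled) grid, in C-raster order (last axis fastest).
    """

    values: np.ndarray
    voxel_index: np.ndarray
    subject_ids: list[str]
    grid_dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("columns do not align with voxel_index")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    voxel_size_mm = np.asarray(voxel_size_mm, dtype=float)
    return (fwhm_mm / voxel_size_mm) / _FWHM_FACTOR


def gaussian_smooth(
    data: np.ndarray, fwhm_mm: float, voxel_size_mm=(2.0, 2.0, 2.0)
) -> np.ndarray:
    """Separable Gaussian smoothing with an isotropic FWHM in millimetres.

    Boundary handling is constant extension ("nearest"), which preserves
    constant volumes exactly; mass (the voxel sum) is preserved away from
    the boundary.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    return ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")


def downsample_by_two(data: np.ndarray) -> np.ndarray:
    """Halve each axis by 2x2x2 block averaging.

    Output dims are floor(input/2); a trailing odd slice per axis is
    discarded (91x109x91 -> 45x54x45).  Each output voxel is the
    arithmetic mean of its 8-voxel block, so constant volumes map to the
    same constant and, for even dims, the global mean is preserved.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if any(d < 2 for d in data.shape):
        raise ValueError("all dims must be >= 2 to downsample")
    nx, ny, nz = (d // 2 for d in data.shape)
    trimmed = data[: 2 * nx, : 2 * ny, : 2 * nz]
    return trimmed.reshape(nx, 2, ny, 2, nz, 2).mean(axis=(1, 3, 5))


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Downsample a boolean mask: an output voxel is kept when at least
    half of its 2x2x2 block is inside the mask."""
    return downsample_by_two(np.asarray(mask, dtype=float)) >= 0.5


def vectorize(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract in-mask voxels as a row vector in C-raster order.

    Returns ``(row, voxel_index)`` where ``voxel_index`` maps each column
    to its (i, j, k) grid coordinate (0-based, last axis fastest).
    """
    data = np.asarray(data)
    mask = np.asarray(mask, dtype=bool)
    if data.shape != mask.shape:
        raise ValueError("mask dims must equal volume dims")
    if not mask.any():
        raise ValueError("mask is empty")
    return data[mask].astype(float), np.argwhere(mask)


def devectorize(
    row: np.ndarray, voxel_index: np.ndarray, grid_dims: tuple[int, int, int]
) -> np.ndarray:
    """Scatter a feature row back onto the grid; out-of-mask voxels are 0."""
    row = np.asarray(row, dtype=float)
    voxel_index = np.asarray(voxel_index, dtype=int)
    if row.shape[0] != voxel_index.shape[0]:
        raise ValueError("row length does not match voxel_index")
    out = np.zeros(grid_dims, dtype=float)
    out[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = row
    return out


def global_mean_scale(row: np.ndarray) -> np.ndarray:
    """Divide a feature row by its mean so the scaled row has mean 1.

    Removes between-subject differences in global signal.  A non-positive
    mean signals a corrupt volume and is rejected.
    """
    row = np.asarray(row, dtype=float)
    m = row.mean()
    if m <= 0:
        raise ValueError(f"global mean must be positive, got {m!r}")
    return row / m


def residualize_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Voxelwise OLS of each column on (intercept, age); returns residuals.

    Every residual column sums to zero and is orthogonal to the centred
    age vector.  All columns share the design matrix, so a single
    least-squares solve handles the whole matrix.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float).ravel()
    if values.shape[0] != ages.shape[0]:
        raise ValueError("ages length must match number of subjects")
    if np.unique(ages).size < 2:
        raise ValueError("all ages identical: design matrix is singular")
    A = np.column_stack([np.ones_like(ages), ages])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return values - A @ coef


class AgeResidualizer:
    """Transformer removing a per-voxel linear age trend.

    ``fit(X, ages)`` estimates intercept and slope per column;
    ``transform(X, ages)`` subtracts the fitted trend.  Fitting inside a
    training fold and applying to the held-out subject gives the
    leakage-free ("fold-safe") variant of age correction.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "AgeResidualizer":
        if params:
            raise ValueError("AgeResidualizer has no parameters")
        return self

    def fit(self, X: np.ndarray, ages: np.ndarray) -> "AgeResidualizer":
        X = np.asarray(X, dtype=float)
        ages = np.asarray(ages, dtype=float).ravel()
        if np.unique(ages).size < 2:
            raise ValueError("all ages identical: design matrix is singular")
        A = np.column_stack([np.ones_like(ages), ages])
        self.coef_, *_ = np.linalg.lstsq(A, X, rcond=None)
        return self

    def transform(self, X: np.ndarray, ages: np.ndarray) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("not fitted")
        ages = np.asarray(ages, dtype=float).ravel()
        A = np.column_stack([np.ones_like(ages), ages])
        return np.asarray(X, dtype=float) - A @ self.coef_

    def fit_transform(self, X: np.ndarray, ages: np.ndarray) -> np.ndarray:
        return self.fit(X, ages).transform(X, ages)


def scale_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Global-mean scale every row of a raw FeatureMatrix (stage raw -> scaled)."""
    if fm.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {fm.stage!r}")
    scaled = np.vstack([global_mean_scale(row) for row in fm.values])
    return replace(fm, values=scaled, stage="scaled")


def residualize_features(fm: FeatureMatrix, ages: np.ndarray) -> FeatureMatrix:
    """Voxelwise age residualization (stage scaled -> residualized).

    Requires at least three distinct ages so the linear fit leaves
    non-trivial residual degrees of freedom.
    """
    if fm.stage != "scaled":
        raise ValueError(f"expected stage 'scaled', got {fm.stage!r}")
    ages = np.asarray(ages, dtype=float).ravel()
    if ages.shape[0] != fm.n_subjects:
        raise ValueError("ages length must match number of subjects")
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    resid = residualize_age(fm.values, ages)
    return replace(fm, values=resid, stage="residualized")


def preprocess_volumes(
    volumes: list[MetabolicVolume],
    mask: np.ndarray,
    fwhm_mm: float = 12.0,
    downsample: bool = True,
    ages: np.ndarray | None = None,
) -> FeatureMatrix:
    """Full preprocessing pipeline on a list of co-registered volumes.

    The brain mask may be supplied at the input grid (it is block-
    downsampled alongside the volumes) or directly at the downsampled
    grid.  When ``ages`` is given the returned matrix is residualized;
    otherwise it stops at the scaled stage (fold-safe workflows
    residualize later, inside each training fold).
    """
    if not volumes:
        raise ValueError("no volumes given")
    dims0 = volumes[0].data.shape
    voxel = volumes[0].voxel_size_mm
    for v in volumes:
        if v.data.shape != dims0:
            raise ValueError("all volumes must share the same grid")

    mask = np.asarray(mask, dtype=bool)
    processed = []
    for v in volumes:
        d = gaussian_smooth(v.data, fwhm_mm, v.voxel_size_mm)
        if downsample:
            d = downsample_by_two(d)
        processed.append(d)
    out_dims = processed[0].shape
    out_voxel = tuple(2 * s for s in voxel) if downsample else tuple(voxel)

    if mask.shape == dims0 and downsample:
        mask = downsample_mask(mask)
    if mask.shape != out_dims:
        raise ValueError(
            f"mask dims {mask.shape} match neither the input grid {dims0} "
            f"nor the working grid {out_dims}"
        )

    rows = []
    voxel_index = None
    for d in processed:
        row, voxel_index = vectorize(d, mask)
        rows.append(row)
    fm = FeatureMatrix(
        values=np.vstack(rows),
        voxel_index=voxel_index,
        subject_ids=[v.subject_id for v in volumes],
        grid_dims=out_dims,
        voxel_size_mm=out_voxel,
        stage="raw",
    )
    fm = scale_features(fm)
    if ages is not None:
        fm = residualize_features(fm, ages)
    return fm
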