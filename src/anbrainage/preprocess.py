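"""Tissue-map preprocessing: Gaussian smoothing, resampling, masking, vectorisation.

The feature-extraction convention mirrors classical voxel-based-morphometry
brain-age pipelines: tissue-probability maps are smoothed at native resolution
with a fixed-FWHM Gaussian, resampled to a coarse isotropic grid (8 mm by
default), restricted to a mask derived from the training sample, and flattened
into one feature row per scan.

Smoothing happens *before* resampling; both steps are intensity-affine
(``preprocess(a*X + b) == a*preprocess(X) + b``), and vectorisation uses a
fixed x-fastest (Fortran) voxel ordering so feature columns are stable across
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ShapeError

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

GM = "GM"
WM = "WM"
TISSUES = (GM, WM)


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a smoothing FWHM in mm to a Gaussian sigma in voxel units."""
    return (fwhm_mm / voxel_size_mm) / FWHM_PER_SIGMA


@dataclass
class VoxelMap:
    """One subject-scan's 3-D tissue map (GM or WM).

    ``affine`` follows the NIfTI convention (voxel index -> world mm);
    synthetic maps use a diagonal affine encoding ``voxel_size_mm``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    tissue: str
    scan_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ShapeError(f"voxel map must be a non-empty 3-D grid, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError(f"voxel map {self.scan_id!r} contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ShapeError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ShapeError("affine must be 4x4")

    @classmethod
    def create(cls, data, voxel_size_mm, tissue, scan_id) -> "VoxelMap":
        """Build a map with a diagonal affine from an isotropic/anisotropic voxel size."""
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (voxel_size_mm,) * 3
        affine = np.diag(list(voxel_size_mm) + [1.0])
        return cls(data=data, voxel_size_mm=tuple(voxel_size_mm), affine=affine,
                   tissue=tissue, scan_id=scan_id)


@dataclass
class FeatureMatrix:
    """n_scans x n_features matrix of masked voxel intensities.

    Row order matches ``scan_ids``; columns are the True voxels of ``mask``
    in x-fastest (Fortran) order.
    """

    values: np.ndarray
    scan_ids: list[str]
    mask: np.ndarray
    tissue: str
    voxel_size_mm: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def smooth_map(vmap: VoxelMap, fwhm_mm: float) -> VoxelMap:
    """Separable Gaussian smoothing with renormalised-truncation boundaries.

    The volume is filtered with zero padding and divided by the identically
    filtered indicator of the volume, so no values are invented outside the
    grid and constants are preserved exactly up to the boundary. ``fwhm_mm=0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(vmap, data=vmap.data.copy())
    sigma = [fwhm_to_sigma(fwhm_mm, v) for v in vmap.voxel_size_mm]
    num = ndimage.gaussian_filter(vmap.data, sigma=sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(np.ones_like(vmap.data), sigma=sigma, mode="constant", cval=0.0)
    return replace(vmap, data=num / den)


def resample_map(vmap: VoxelMap, target_mm: float) -> VoxelMap:
    """Trilinear resampling onto an isotropic grid at ``target_mm``.

    Output voxel centres lie on ``j * target_mm`` along each axis measured
    from the first input voxel centre and never extrapolate beyond the input
    field of view. When the target equals the source resolution the grids
    coincide and the data pass through unchanged.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    vs = vmap.voxel_size_mm
    shape = vmap.data.shape
    if all(np.isclose(v, target_mm) for v in vs):
        return replace(vmap, data=vmap.data.copy())
    n_out = [int(np.floor((n - 1) * v / target_mm)) + 1 for n, v in zip(shape, vs)]
    coords1d = [np.arange(n) * target_mm / v for n, v in zip(n_out, vs)]
    grid = np.meshgrid(*coords1d, indexing="ij")
    data = ndimage.map_coordinates(vmap.data, np.stack(grid), order=1, mode="nearest")
    scale = np.diag([target_mm / vs[0], target_mm / vs[1], target_mm / vs[2], 1.0])
    return replace(
        vmap,
        data=data,
        voxel_size_mm=(target_mm,) * 3,
        affine=vmap.affine @ scale,
    )


def make_mask(training_maps: list[VoxelMap], threshold: float = 0.05) -> np.ndarray:
    """Voxel inclusion mask: mean training intensity strictly above ``threshold``.

    The mask is computed from training data only and must be reused, frozen,
    for test data.
    """
    if not training_maps:
        raise ValueError("need at least one training map")
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    shape = training_maps[0].data.shape
    for m in training_maps:
        if m.data.shape != shape:
            raise ShapeError(f"map {m.scan_id!r} has shape {m.data.shape}, expected {shape}")
    mean = np.mean([m.data for m in training_maps], axis=0)
    return mean > threshold


def vectorize(maps: list[VoxelMap], mask: np.ndarray) -> FeatureMatrix:
    """Flatten masked voxels into one feature row per scan (x-fastest order)."""
    if not maps:
        raise ValueError("need at least one map")
    flat_mask = np.asarray(mask, dtype=bool).ravel(order="F")
    if not flat_mask.any():
        raise EmptyMaskError("mask selects no voxels")
    shape = np.asarray(mask).shape
    rows, scan_ids = [], []
    for m in maps:
        if m.data.shape != shape:
            raise ShapeError(f"map {m.scan_id!r} has shape {m.data.shape}, mask has {shape}")
        rows.append(m.data.ravel(order="F")[flat_mask])
        scan_ids.append(m.scan_id)
    tissue = maps[0].tissue
    return FeatureMatrix(values=np.vstack(rows), scan_ids=scan_ids,
                         mask=np.asarray(mask, dtype=bool), tissue=tissue,
                         voxel_size_mm=maps[0].voxel_size_mm)


def unvectorize(row: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter one feature row back into a 3-D grid (zeros off-mask)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.size, dtype=float)
    out[mask.ravel(order="F")] = row
    return out.reshape(mask.shape, order="F")


def preprocess_maps(
    maps: list[VoxelMap],
    fwhm_mm: float = 8.0,
    target_mm: float = 8.0,
    fwhm_post_mm: float = 0.0,
) -> list[VoxelMap]:
    """Smooth at native resolution, then resample; optional second smoothing pass."""
    out = []
    for m in maps:
        s = smooth_map(m, fwhm_mm)
        r = resample_map(s, target_mm)
        if fwhm_post_mm > 0:
            r = smooth_map(r, fwhm_post_mm)
        out.append(r)
    return out
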