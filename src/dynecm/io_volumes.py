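"""Volumetric I/O and the image-space <-> matrix-space bridge.

A 4D resting-state series is analysed as an ``n_voxels x T`` matrix restricted
to a grey-matter analysis mask.  The mask fixes a deterministic voxel ordering
(lexicographic by (x, y, z), x slowest) so that every downstream vector — a
centrality map, a template column, a statistic map — indexes voxels the same
way on every run and platform.  Out-of-mask voxels are written as 0, the usual
convention for volumetric statistic maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGeometry",
    "AnalysisMask",
    "MaskedSeries",
    "build_mask",
    "extract_series",
    "insert_maps",
    "load_volume",
    "save_mask",
    "save_maps",
]


class EmptyMaskError(ValueError):
    """No voxel survived the probability threshold."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Spatial grid of a volume: shape in voxels plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive dimensions, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length per axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGeometry):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.round(6).tobytes()))


@dataclass(frozen=True)
class AnalysisMask:
    """Ordered set of in-mask voxel coordinates on a fixed grid.

    ``voxel_indices`` is an ``(n_voxels, 3)`` integer array sorted
    lexicographically by (x, y, z) with x slowest — the order produced by
    ``np.argwhere`` on a C-ordered array.  The ordering is part of the
    contract: row i of every masked matrix refers to ``voxel_indices[i]``.
    """

    geometry: VolumeGeometry
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_indices must be (n, 3)")
        if idx.shape[0] == 0:
            raise EmptyMaskError("mask has no voxels")
        shape = np.asarray(self.geometry.shape)
        if (idx < 0).any() or (idx >= shape).any():
            raise ValueError("voxel indices outside grid")
        # enforce canonical lexicographic order and uniqueness
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        idx = idx[order]
        if (np.diff(np.ravel_multi_index(idx.T, self.geometry.shape)) == 0).any():
            raise ValueError("duplicate voxel indices in mask")
        idx.setflags(write=False)
        object.__setattr__(self, "voxel_indices", idx)

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def flat_indices(self) -> np.ndarray:
        """C-order flat indices of the mask voxels (same ordering)."""
        return np.ravel_multi_index(self.voxel_indices.T, self.geometry.shape)

    def to_volume(self) -> np.ndarray:
        """Binary 3D array with 1 at in-mask voxels."""
        vol = np.zeros(self.geometry.shape, dtype=np.uint8)
        vol.flat[self.flat_indices] = 1
        return vol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisMask):
            return NotImplemented
        return self.geometry == other.geometry and np.array_equal(
            self.voxel_indices, other.voxel_indices
        )

    def __hash__(self) -> int:
        return hash((self.geometry, self.voxel_indices.tobytes()))


@dataclass
class MaskedSeries:
    """A subject's in-mask voxel x time data matrix.

    ``data[i]`` is the time series of ``mask.voxel_indices[i]``.  After
    row-wise z-scoring, ``zero_variance`` flags rows that were constant
    (mapped to all-zero rows).
    """

    mask: AnalysisMask
    data: np.ndarray  # n_voxels x T
    tr_seconds: float = 2.0
    zero_variance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (n_voxels x T)")
        if self.data.shape[0] != self.mask.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def build_mask(
    gm_probability_map: np.ndarray,
    geometry: VolumeGeometry,
    threshold: float = 0.2,
) -> AnalysisMask:
    """Threshold a grey-matter probability map into an analysis mask.

    A voxel is included iff its probability is *strictly* greater than
    ``threshold`` (default 0.2, the usual grey-matter cut on a CAT12-style
    segmentation).
    """
    prob = np.asarray(gm_probability_map, dtype=float)
    if prob.shape != geometry.shape:
        raise ValueError(f"map shape {prob.shape} != geometry shape {geometry.shape}")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    idx = np.argwhere(prob > threshold)
    if idx.shape[0] == 0:
        raise EmptyMaskError(
            f"empty mask: no voxel exceeds probability threshold {threshold}"
        )
    return AnalysisMask(geometry=geometry, voxel_indices=idx)


def extract_series(
    image_4d: np.ndarray,
    mask: AnalysisMask,
    tr_seconds: float = 2.0,
) -> MaskedSeries:
    """Pull the in-mask time series out of a 4D image into a matrix."""
    img = np.asarray(image_4d, dtype=np.float64)
    if img.ndim != 4:
        raise ValueError("expected a 4D image")
    if img.shape[:3] != mask.geometry.shape:
        raise ValueError(
            f"image spatial shape {img.shape[:3]} != mask geometry "
            f"{mask.geometry.shape}"
        )
    flat = img.reshape(-1, img.shape[3])
    return MaskedSeries(mask=mask, data=flat[mask.flat_indices], tr_seconds=tr_seconds)


def insert_maps(values: np.ndarray, mask: AnalysisMask) -> np.ndarray:
    """Write an ``n_voxels x k`` matrix back into a 4D image (k volumes).

    Out-of-mask voxels are 0.  A 1D input is treated as a single column.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.ndim != 2 or vals.shape[0] != mask.n_voxels:
        raise ValueError(
            f"values must have {mask.n_voxels} rows, got shape {vals.shape}"
        )
    k = vals.shape[1]
    out = np.zeros(mask.geometry.shape + (k,), dtype=np.float64)
    out.reshape(-1, k)[mask.flat_indices] = vals
    return out


# ---------------------------------------------------------------------------
# NIfTI boundary


def load_volume(path) -> tuple[np.ndarray, VolumeGeometry]:
    """Read a NIfTI volume; returns (data array, geometry)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    geom = VolumeGeometry(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))
    return data, geom


def save_mask(mask: AnalysisMask, path) -> None:
    """Write a binary mask as uint8 NIfTI."""
    img = nib.Nifti1Image(mask.to_volume(), mask.geometry.affine)
    nib.save(img, str(path))


def save_maps(values: np.ndarray, mask: AnalysisMask, path) -> None:
    """Write masked values as float32 NIfTI (3D for one column, else 4D)."""
    vol = insert_maps(values, mask)
    if vol.shape[3] == 1:
        vol = vol[..., 0]
    img = nib.Nifti1Image(vol.astype(np.float32), mask.geometry.affine)
    nib.save(img, str(path))
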