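"""Shared volumetric data model and spatial primitives.

All volumes are 3D arrays in ``(z, y, x)`` axis order with physical voxel
spacing ``(dz, dy, dx)`` in micrometres.  Every distance-valued quantity in
this package is expressed in µm; filters take their scales in µm and convert
to per-axis voxel units internally, so anisotropic voxel grids are handled
correctly throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "LabelVolume",
    "DistanceField",
    "distance_transform",
    "gaussian_gradient",
    "connected_components",
    "surface_voxels",
]

Spacing = tuple[float, float, float]


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must be a (dz, dy, dx) triple")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing values must be positive and finite, got {spacing}")
    return spacing


def _check_shape(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"volume must be 3D (z, y, x), got ndim={data.ndim}")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"every axis must have length >= 1, got shape {data.shape}")


@dataclass
class VolumeGrid:
    """A 3D scalar field (intensity in arbitrary units) on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities.
    spacing : (dz, dy, dx), µm
        Physical voxel spacing; strictly positive.
    """

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_shape(self.data)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def coords_to_index(self, point) -> tuple[int, int, int]:
        """Nearest-voxel index of a physical (z, y, x) µm coordinate."""
        idx = np.rint(np.asarray(point, dtype=float) / np.asarray(self.spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise ValueError(f"point {tuple(point)} µm falls outside the grid")
        return tuple(int(i) for i in idx)


@dataclass
class MaskVolume:
    """Binary 3D mask with the same shape/spacing contract as VolumeGrid."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_shape(self.data)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """Non-negative integer label field; 0 is background."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        _check_shape(self.data)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive label ids present in the volume."""
        ids = np.unique(self.data)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance (µm) to a source mask; 0 on the source."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    source_mask: Optional[MaskVolume] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_shape(self.data)
        self.spacing = _check_spacing(self.spacing)
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("distance field must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def value_at(self, point, interpolate: bool = False) -> float:
        """Field value at a physical (z, y, x) µm coordinate.

        Nearest-voxel lookup by default; set ``interpolate`` for trilinear.
        """
        if interpolate:
            coords = np.asarray(point, dtype=float) / np.asarray(self.spacing)
            if np.any(coords < 0) or np.any(coords > np.asarray(self.shape) - 1):
                raise ValueError(f"point {tuple(point)} µm falls outside the grid")
            return float(ndi.map_coordinates(self.data, coords[:, None], order=1)[0])
        grid = VolumeGrid(self.data, self.spacing)
        return float(self.data[grid.coords_to_index(point)])


def distance_transform(mask: MaskVolume, spacing: Optional[Spacing] = None) -> DistanceField:
    """Spacing-aware Euclidean distance (µm) to the nearest foreground voxel.

    Parameters
    ----------
    mask : MaskVolume
        Source set; must contain at least one foreground voxel.
    spacing : optional (dz, dy, dx) µm
        Overrides ``mask.spacing``. Pass ``(1, 1, 1)`` for voxel-unit
        (spacing-unaware) distances.
    """
    if not mask.data.any():
        raise ValueError("distance_transform requires a non-empty mask (no distance source)")
    sp = _check_spacing(spacing) if spacing is not None else mask.spacing
    dist = ndi.distance_transform_edt(~mask.data, sampling=sp)
    return DistanceField(dist, sp, source_mask=mask)


def gaussian_gradient(volume: VolumeGrid, sigma: float, mode: str = "reflect") -> np.ndarray:
    """Gaussian-derivative gradient of a volume, ∇I = I * ∇G.

    ``sigma`` is the kernel standard deviation in µm; it is converted to
    per-axis voxel sigmas using the grid spacing, and the derivatives are
    returned in intensity per µm.

    Returns
    -------
    ndarray, shape (3, nz, ny, nx)
        Components (∂I/∂z, ∂I/∂y, ∂I/∂x).
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0 µm, got {sigma}")
    if any(s < 3 for s in volume.shape):
        raise ValueError("gaussian_gradient needs at least 3 voxels per axis")
    data = np.asarray(volume.data, dtype=float)
    sp = np.asarray(volume.spacing)
    sigma_vox = sigma / sp
    grad = np.empty((3,) + volume.shape, dtype=float)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        # derivative w.r.t. voxel index, then rescale to per-µm
        grad[axis] = ndi.gaussian_filter(data, sigma_vox, order=order, mode=mode) / sp[axis]
    return grad


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-connectivity."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, got {connectivity}")
    return ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def connected_components(mask: MaskVolume, connectivity: int = 26) -> LabelVolume:
    """Label connected foreground components (deterministic raster order)."""
    structure = connectivity_structure(connectivity)
    labels, _ = ndi.label(mask.data, structure=structure)
    return LabelVolume(labels, mask.spacing)


def surface_voxels(mask: MaskVolume) -> MaskVolume:
    """Foreground voxels with at least one background face-neighbor.

    The volume border counts as background, so a mask touching the border has
    surface voxels there too.
    """
    eroded = ndi.binary_erosion(
        mask.data, structure=ndi.generate_binary_structure(3, 1), border_value=0
    )
    return MaskVolume(mask.data & ~eroded, mask.spacing)
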