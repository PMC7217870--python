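"""Voxel grids and 3D scalar maps (betas, t/Z maps, masks, weights).

A :class:`VoxelGrid` is a shape plus an affine mapping voxel indices to
millimetre coordinates; a :class:`VoxelMap` is a 3D field on such a grid
with an optional boolean mask (values outside the mask are NaN).  NIfTI-1
round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    shape: tuple[int, int, int]
    voxel_size: float = 3.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        # centre the grid on the origin, mirroring a common-space bounding box
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class VoxelMap:
    data: np.ndarray
    grid: VoxelGrid
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid {self.grid.shape}")
        if self.mask is not None and self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape mismatch")

    def masked_values(self) -> np.ndarray:
        """Values inside the mask in C (row-major) voxel order."""
        m = np.ones(self.grid.shape, bool) if self.mask is None else self.mask
        return self.data[m]

    def same_grid(self, other: "VoxelMap") -> bool:
        return (tuple(self.grid.shape) == tuple(other.grid.shape)
                and np.isclose(self.grid.voxel_size, other.grid.voxel_size))


def save_map(vmap: VoxelMap, path) -> None:
    data = vmap.data.copy()
    nib.save(nib.Nifti1Image(data.astype(np.float32), vmap.grid.affine), str(path))


def load_map(path, mask: np.ndarray | None = None) -> VoxelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    vs = float(np.abs(img.affine[0, 0]))
    grid = VoxelGrid(tuple(int(s) for s in data.shape[:3]), voxel_size=vs)
    return VoxelMap(data=data, grid=grid, mask=mask)


def save_bold(runs: list[np.ndarray], grid: VoxelGrid, tr: float, path) -> None:
    """Write run-concatenated 4D BOLD as a single NIfTI-1 file."""
    vol = np.concatenate(runs, axis=3).astype(np.float32)
    img = nib.Nifti1Image(vol, grid.affine)
    img.header.set_zooms((grid.voxel_size,) * 3 + (tr,))
    nib.save(img, str(path))


def load_bold(path) -> tuple[np.ndarray, VoxelGrid, float]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    vs = float(np.abs(img.affine[0, 0]))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    grid = VoxelGrid(tuple(int(s) for s in data.shape[:3]), voxel_size=vs)
    return data, grid, tr
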