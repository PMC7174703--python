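"""Voxel-grid containers shared by every stage of the pipeline.

A :class:`VoxelGrid` is a 3D scalar array with physical metadata: the edge
lengths of one voxel in micrometres and the physical position of the grid's
(0, 0, 0) corner. Axis order is (x, y, z) with z the horizontal-section
index, matching block-face imaging conventions. The physical coordinate of
the *centre* of voxel (i, j, k) is ``origin + ((i, j, k) + 0.5) * voxel_size``.

``LabelGrid`` is the same container holding integer labels (0 = background,
k = voxels of cell k) and always shares its partner grid's geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "LabelGrid"]


@dataclass
class VoxelGrid:
    """3D intensity volume with physical voxel size and origin (μm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # bright-field Nissl: stained somata darker than background
    polarity: str = "dark_cells"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        self.origin = tuple(float(v) for v in self.origin)
        if self.polarity not in ("dark_cells", "bright_cells"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths of the whole grid (μm)."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))

    def voxel_to_world(self, index) -> np.ndarray:
        """Physical coordinates (μm) of voxel centres for integer indices."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def world_to_voxel(self, xyz_um) -> np.ndarray:
        """Integer index of the voxel containing a physical point."""
        p = np.asarray(xyz_um, dtype=float)
        rel = (p - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        return np.floor(rel).astype(int)

    def contains_point(self, xyz_um) -> bool:
        idx = self.world_to_voxel(xyz_um)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.voxel_size, self.origin, self.polarity)


# A LabelGrid is structurally a VoxelGrid whose data are integer cell ids.
LabelGrid = VoxelGrid
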