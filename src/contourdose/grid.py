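"""Voxel grids, binary structure masks and structure sets.

All geometry in this package lives on a regular 3D voxel grid with physical
spacing in millimetres.  Indices are 0-based and the centre of voxel
``(i, j, k)`` sits at ``origin + index * spacing``; every metric quantity
(distances, volumes) is expressed in physical mm, never in voxel units.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import IncompatibleGridsError

__all__ = ["VoxelGrid", "StructureMask", "StructureSet"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular, axis-aligned voxel lattice with physical spacing.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; all components >= 1.
    spacing : tuple of float
        Voxel pitch along each axis in mm; all components > 0.
    origin : tuple of float
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must each have 3 components")
        if any(s < 1 for s in shape):
            raise ValueError(f"grid shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of a voxel body diagonal — the natural discretisation scale."""
        return float(np.linalg.norm(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def center_mm(self) -> np.ndarray:
        """Physical centre of the grid extent."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return (lo + hi) / 2.0

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable per-axis centre coordinates (for vectorised rasterisation)."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def indices_to_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to physical coordinates in mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains_point(self, point_mm) -> bool:
        """Whether a physical point lies inside the grid extent.

        The extent is the voxel-centre bounding box padded by half a voxel on
        every side, i.e. the union of all voxel volumes.
        """
        p = np.asarray(point_mm, dtype=float)
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return bool(np.all(p >= lo) and np.all(p <= hi))


def make_grid(shape, spacing, origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Construct a :class:`VoxelGrid`, validating shape and spacing."""
    return VoxelGrid(tuple(shape), tuple(spacing), tuple(origin))


@dataclass
class StructureMask:
    """Binary voxel occupancy of one anatomical structure on a grid."""

    grid: VoxelGrid
    voxels: np.ndarray
    name: str
    role: str = "oar"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid shape {self.grid.shape}"
            )
        if not self.name:
            raise ValueError("structure name must be non-empty")
        if self.role not in ("target", "oar"):
            raise ValueError(f"role must be 'target' or 'oar', got {self.role!r}")

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise ValueError(f"centroid undefined for empty structure {self.name!r}")
        idx = np.argwhere(self.voxels)
        return self.grid.indices_to_mm(idx).mean(axis=0)

    def with_voxels(self, voxels: np.ndarray) -> "StructureMask":
        return StructureMask(self.grid, voxels, self.name, self.role)

    def require_same_grid(self, other: "StructureMask") -> None:
        if self.grid != other.grid:
            raise IncompatibleGridsError(
                f"masks {self.name!r} and {other.name!r} are on different grids"
            )


@dataclass
class StructureSet:
    """A named collection of structure masks sharing one grid (one subject)."""

    subject_id: str
    source: str  # "MS" (manual, treated as truth) or "AS" (auto-segmented)
    structures: dict[str, StructureMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("MS", "AS"):
            raise ValueError(f"source must be 'MS' or 'AS', got {self.source!r}")
        grids = {m.grid for m in self.structures.values()}
        if len(grids) > 1:
            raise IncompatibleGridsError(
                f"structure set {self.subject_id!r} mixes masks from different grids"
            )
        for name, mask in self.structures.items():
            if mask.name != name:
                raise ValueError(f"key {name!r} does not match mask name {mask.name!r}")

    @property
    def grid(self) -> VoxelGrid:
        if not self.structures:
            raise ValueError("structure set is empty")
        return next(iter(self.structures.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.structures)

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not in set {self.subject_id!r} "
                f"(has: {', '.join(self.structures) or 'none'})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __iter__(self) -> Iterator[StructureMask]:
        return iter(self.structures.values())
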