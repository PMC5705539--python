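"""Voxel containers: scalar fields on a regular grid and binary VOI masks.

Conventions: voxel indices are 0-based; world coordinates are millimetres with
the origin at the grid corner, so voxel (i, j, k) is centred at
((i + 0.5) * dx, (j + 0.5) * dy, (k + 0.5) * dz). Density is 1 g/mL
everywhere, so a voxel's mass in grams equals its volume in mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_UNITS = ("Bq/mL", "Gy", "counts", "unknown")


class GeometryError(ValueError):
    """A shape/voxel-size mismatch or an object falling outside the grid."""


class UnitError(ValueError):
    """An operation received a grid in the wrong physical unit."""


@dataclass
class VoxelGrid:
    """A 3D scalar field with voxel dimensions and a unit tag.

    ``values`` holds one scalar per voxel (activity concentration in Bq/mL,
    absorbed dose in Gy, or detected counts); ``voxel_size_mm`` is the
    (dx, dy, dz) voxel pitch in millimetres.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    unit: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(f"values must be 3D, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(
                f"voxel_size_mm must be three positive floats, got {self.voxel_size_mm}"
            )
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must all be finite")
        if self.unit == "counts" and np.any(self.values < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mL(self) -> float:
        """Voxel volume in mL (= cm^3): product of the mm pitches / 1000."""
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VoxelGrid":
        """New grid sharing this geometry, with different values/unit."""
        return VoxelGrid(values, self.voxel_size_mm, unit if unit is not None else self.unit)


@dataclass
class VOIMask:
    """Binary volume-of-interest mask sharing a :class:`VoxelGrid` geometry."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GeometryError(f"mask must be 3D, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GeometryError(
                f"voxel_size_mm must be three positive floats, got {self.voxel_size_mm}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def voxel_volume_mL(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * self.voxel_volume_mL


def check_same_geometry(grid: VoxelGrid, mask: VOIMask, *, require_nonempty: bool = True) -> None:
    """Raise unless ``mask`` matches ``grid`` in shape and voxel size."""
    if grid.shape != mask.shape:
        raise GeometryError(f"shape mismatch: image {grid.shape} vs mask {mask.shape}")
    if not np.allclose(grid.voxel_size_mm, mask.voxel_size_mm, rtol=1e-6, atol=0):
        raise GeometryError(
            f"voxel size mismatch: image {grid.voxel_size_mm} vs mask {mask.voxel_size_mm}"
        )
    if require_nonempty and mask.n_voxels == 0:
        raise ValueError("mask is empty")


def masked_values(grid: VoxelGrid, mask: VOIMask) -> np.ndarray:
    """Values of ``grid`` inside ``mask`` after geometry validation."""
    check_same_geometry(grid, mask)
    return grid.values[mask.values]
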