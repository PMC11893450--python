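"""Voxel raster container shared by dose, initial-pressure and reconstructed volumes.

Conventions: right-handed world frame in mm; voxel indices are 0-based and map to
world coordinates via ``origin + index * spacing`` (voxel-center convention).
Arrays are indexed ``values[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel raster: shape, isotropic-or-not spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats (mm), got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def isotropic(cls, shape, spacing_mm: float, origin=(0.0, 0.0, 0.0)) -> "GridSpec":
        return cls(tuple(shape), (spacing_mm,) * 3, tuple(origin))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center world coordinates, shape ``shape + (3,)``."""
        ax = [self.axis_coords(i) for i in range(3)]
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """True where world points lie within the voxel-center bounding box
        (with a tiny tolerance against floating-point edge effects)."""
        idx = self.world_to_index(points)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= -tol) & (idx <= hi + tol), axis=-1)


@dataclass
class Volume:
    """A scalar field on a :class:`GridSpec` raster.

    Used for deposited dose per pulse (``DoseGrid``), initial pressure p0 and
    reconstructed relative pressure; values are in arbitrary linear units.
    """

    values: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    def with_values(self, values: np.ndarray, **provenance) -> "Volume":
        return Volume(values, self.grid, {**self.provenance, **provenance})

    def argmax_world(self) -> np.ndarray:
        """World coordinates (mm) of the voxel with the maximum value."""
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return self.grid.index_to_world(np.asarray(idx, dtype=float))

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the field at world points (..., 3)."""
        from scipy.ndimage import map_coordinates

        idx = self.grid.world_to_index(points)
        flat = idx.reshape(-1, 3).T
        out = map_coordinates(self.values, flat, order=1, mode="nearest")
        return out.reshape(np.asarray(points).shape[:-1])

    def translated(self, shift_mm) -> "Volume":
        """Same field with the raster origin translated by ``shift_mm``."""
        new_origin = tuple(np.asarray(self.origin) + np.asarray(shift_mm, dtype=float))
        return Volume(self.values.copy(), replace(self.grid, origin=new_origin),
                      dict(self.provenance))


DoseGrid = Volume
InitialPressureVolume = Volume
ReconVolume = Volume
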