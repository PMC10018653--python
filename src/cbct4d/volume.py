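"""Scalar volumes, 10-phase volume sets and deformation vector fields.

Conventions used throughout the package:

* arrays are indexed ``[ix, iy, iz]`` with x = patient left-right,
  y = anterior-posterior and z = inferior-superior (SI) in mm;
* voxel ``(i, j, k)`` is centred at ``origin + (i*sx, j*sy, k*sz)``;
* the internal intensity unit is linear attenuation in mm^-1
  (:func:`mu_to_hu` provides a display-only HU mapping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

MU_WATER = 0.020
"""Linear attenuation of water-equivalent soft tissue (mm^-1) used by the HU map."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D sampling grid: shape, isotropic-or-not spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid dimensions must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @classmethod
    def centered(cls, shape: Sequence[int], spacing: Sequence[float]) -> "GridSpec":
        """Grid whose centre coincides with the world origin (the isocenter)."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world coordinates (…, 3) to fractional voxel indices."""
        return (np.asarray(pts) - np.array(self.origin)) / np.array(self.spacing)

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (low, high) world coordinates of the sampled domain."""
        return tuple(
            (self.origin[a], self.origin[a] + (self.shape[a] - 1) * self.spacing[a])
            for a in range(3)
        )


@dataclass(frozen=True)
class Box:
    """Axis-aligned voxel box, ``lo`` inclusive and ``hi`` exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def inside(self, grid_shape: Sequence[int]) -> bool:
        return all(
            0 <= l < h <= n for l, h, n in zip(self.lo, self.hi, grid_shape)
        )

    def extract(self, values: np.ndarray) -> np.ndarray:
        return values[self.slices]


@dataclass
class Volume:
    """3D scalar attenuation image on a :class:`GridSpec`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume.values must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.values.shape), self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing, self.origin)

    def like(self, values: np.ndarray) -> "Volume":
        """New volume with the same geometry and different values."""
        return Volume(np.asarray(values), self.spacing, self.origin)


@dataclass
class Volume4D:
    """Ordered respiratory-phase set of volumes sharing one grid."""

    phases: list[Volume]
    phase_fractions: list[float]
    peak_inhale: int = 0

    def __post_init__(self):
        if len(self.phases) != len(self.phase_fractions):
            raise ValueError("one phase fraction per volume required")
        g0 = self.phases[0].grid
        for v in self.phases[1:]:
            if v.grid != g0:
                raise ValueError("all phases must share grid geometry")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def grid(self) -> GridSpec:
        return self.phases[0].grid

    def mean(self) -> Volume:
        """Time-averaged volume (the '3D' companion of a 4D scan)."""
        stack = np.stack([p.values for p in self.phases], axis=0)
        return self.phases[0].like(stack.mean(axis=0))

    def __getitem__(self, k: int) -> Volume:
        return self.phases[k]

    def __len__(self) -> int:
        return len(self.phases)


@dataclass
class DVF:
    """Displacement vector field (mm), pull convention.

    ``warp(vol, dvf)`` produces ``out(x) = vol(x + d(x))``: the vector stored at
    an output voxel points at the input-image location to sample.  ``vectors``
    has shape ``(nx, ny, nz, 3)`` on the same grid as the volumes it warps.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    from_phase: int = 0
    to_phase: int = 0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DVF.vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DVF contains non-finite displacements")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.vectors.shape[:3]), self.spacing, self.origin)

    def copy(self) -> "DVF":
        return DVF(self.vectors.copy(), self.spacing, self.origin,
                   self.from_phase, self.to_phase)


def mu_to_hu(values: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Affine attenuation -> Hounsfield-unit map, for display only."""
    return 1000.0 * (np.asarray(values) - mu_water) / mu_water
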