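"""Physical 3D grids: CT-number volumes and boolean masks.

A :class:`Volume3D` is a scalar grid of CT numbers (Hounsfield units, HU)
with per-axis voxel spacing and a physical origin.  Axes are ordered
``(x, y, z)`` with ``z`` the superior/inferior direction; the physical
position of voxel ``(i, j, k)`` (its *center*) is ``origin + index * spacing``.

Two grids are *grid-compatible* when shape, spacing and origin agree to
within ``GRID_TOL`` millimetres; gamma comparison requires compatibility and
:func:`resample_to_grid` is the escape hatch when it does not hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

#: agreement tolerance (mm) for shapes/spacings/origins of two grids
GRID_TOL = 1e-6

#: HU assigned to space outside a volume's physical extent (air)
AIR_HU = -1000.0


@dataclass
class Volume3D:
    """A 3D scalar grid of CT numbers with physical geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def grid_compatible(self, other: "Volume3D | Mask3D", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(values, self.spacing, self.origin)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical (mm) coordinates of voxel-center indices, shape (..., 3)."""
        return np.asarray(index, dtype=float) * np.array(self.spacing) + np.array(self.origin)


@dataclass
class Mask3D:
    """A boolean mask on the grid of an associated :class:`Volume3D`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.values.sum())

    def grid_compatible(self, other: "Volume3D | Mask3D", tol: float = GRID_TOL) -> bool:
        return Volume3D.grid_compatible(self, other, tol)  # type: ignore[arg-type]

    def with_values(self, values: np.ndarray, provenance: dict[str, Any] | None = None) -> "Mask3D":
        return Mask3D(values, self.spacing, self.origin, provenance or dict(self.provenance))


def physical_extent(vol: Volume3D | Mask3D) -> list[tuple[float, float]]:
    """Per-axis physical range [first voxel center, last voxel center] in mm."""
    return [
        (o, o + (n - 1) * s)
        for o, s, n in zip(vol.origin, vol.spacing, vol.shape)
    ]


def resample_to_grid(vol: Volume3D, target: Volume3D | Mask3D, fill: float = AIR_HU) -> Volume3D:
    """Trilinearly resample ``vol`` onto the grid of ``target``.

    Voxels of the target grid falling outside the physical extent of ``vol``
    are filled with ``fill`` (default −1000 HU, air).  Raises ``ValueError``
    if the two physical extents do not overlap on some axis.
    """
    if vol.grid_compatible(target):
        return Volume3D(vol.values.copy(), vol.spacing, vol.origin)

    ext_v = physical_extent(vol)
    ext_t = physical_extent(target)
    for ax, ((v0, v1), (t0, t1)) in enumerate(zip(ext_v, ext_t)):
        if t1 < v0 or t0 > v1:
            raise ValueError(f"no physical overlap between volumes on axis {ax}")

    idx = np.indices(target.shape, dtype=float)
    coords = [
        (target.origin[a] + idx[a] * target.spacing[a] - vol.origin[a]) / vol.spacing[a]
        for a in range(3)
    ]
    out = ndimage.map_coordinates(
        vol.values.astype(np.float64), coords, order=1, mode="constant", cval=fill
    )
    return Volume3D(out, target.spacing, target.origin)
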