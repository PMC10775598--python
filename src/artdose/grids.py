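"""Core lattice types: scalar dose grids and binary structure masks.

All arrays use (z, y, x) axis order with 0-based indices.  World
coordinates are defined at voxel centers: ``world = origin + index * spacing``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

__all__ = ["Grid3D", "Mask3D", "StructureSet", "StructureRole"]


class StructureRole(str, Enum):
    CTV = "CTV"
    PTV = "PTV"
    OAR = "OAR"
    BODY = "BODY"
    DERIVED = "DERIVED"


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned 3D scalar field (dose in Gy).

    Parameters
    ----------
    values
        Dose per voxel, shape (nz, ny, nx); finite and non-negative.
    spacing
        Per-axis voxel size in mm, (z, y, x); strictly positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("Grid3D values must be a 3D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("Grid3D values must be finite")
        if np.any(values < 0):
            raise ValueError("Grid3D values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive values")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_lattice(self, other: "Grid3D | Mask3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "Grid3D":
        return Grid3D(values, self.spacing, self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class Mask3D:
    """Binary structure volume on the same lattice as a companion :class:`Grid3D`."""

    flags: np.ndarray
    name: str = ""
    role: StructureRole = StructureRole.DERIVED
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    warning: str | None = None

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags)
        if flags.ndim != 3:
            raise ValueError("Mask3D flags must be a 3D array")
        flags = flags.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive values")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "role", StructureRole(self.role))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())

    def is_empty(self) -> bool:
        return not bool(self.flags.any())

    def with_flags(self, flags: np.ndarray, name: str | None = None,
                   role: StructureRole | None = None,
                   warning: str | None = None) -> "Mask3D":
        return Mask3D(
            flags,
            name=self.name if name is None else name,
            role=self.role if role is None else role,
            spacing=self.spacing,
            origin=self.origin,
            warning=warning,
        )


@dataclass
class StructureSet:
    """Ordered, named collection of masks sharing one lattice."""

    masks: dict[str, Mask3D] = field(default_factory=dict)

    def add(self, mask: Mask3D) -> None:
        if not mask.name:
            raise ValueError("mask must be named before adding to a StructureSet")
        self.masks[mask.name] = mask

    def __getitem__(self, name: str) -> Mask3D:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[Mask3D]:
        return iter(self.masks.values())

    def __len__(self) -> int:
        return len(self.masks)

    def names(self) -> list[str]:
        return list(self.masks.keys())

    def by_role(self, role: StructureRole) -> list[Mask3D]:
        return [m for m in self.masks.values() if m.role == role]
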