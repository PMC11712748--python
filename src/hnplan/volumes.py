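"""Shared voxel containers: scalar volumes and co-registered structure sets.

Conventions used throughout the package:

* Patient coordinates are millimetres with axes ordered
  (x: patient-left, y: posterior, z: superior) — the common DICOM patient
  system for a head-first supine patient.
* Arrays are indexed ``values[ix, iy, iz]`` so array axis *k* is patient
  axis *k*; voxel indices are 0-based.
* ``origin_mm`` is the patient-space position of the centre of voxel
  (0, 0, 0); voxel *i* along axis *k* is centred at
  ``origin[k] + i * spacing[k]``.
* Structure volumes are computed by voxel counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "VoxelVolume",
    "StructureSet",
    "Role",
    "STANDARD_STRUCTURES",
    "LANDMARK_STRUCTURES",
]


class Role(str, Enum):
    PTV = "PTV"
    CTV = "CTV"
    OAR = "OAR"
    BODY = "BODY"
    LANDMARK = "LANDMARK"


#: The ten modeled head-and-neck structures and their roles.
STANDARD_STRUCTURES: dict[str, Role] = {
    "ptv": Role.PTV,
    "ctv": Role.CTV,
    "brainstem": Role.OAR,
    "cord_plus_5mm": Role.OAR,
    "parotid_l": Role.OAR,
    "parotid_r": Role.OAR,
    "oral_cavity": Role.OAR,
    "larynx": Role.OAR,
    "pharynx": Role.OAR,
    "mandible": Role.OAR,
}

LANDMARK_STRUCTURES: tuple[str, ...] = ("lungs", "shoulders")


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid (HU, Gy or unitless) on a regular voxel lattice.

    Shape, spacing and origin are immutable after creation and the value
    array is marked read-only; derived volumes (e.g. dose) are new objects.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        origin = tuple(float(o) for o in self.origin_mm)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Patient-space coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box (voxel faces, not centres) of the grid."""
        origin = np.asarray(self.origin_mm)
        spacing = np.asarray(self.spacing_mm)
        lo = origin - spacing / 2.0
        hi = origin + (np.asarray(self.shape) - 0.5) * spacing
        return lo, hi

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        pos_mm = np.asarray(pos_mm, dtype=float)
        return (pos_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_grid_as(self, other: "VoxelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VoxelVolume":
        return VoxelVolume(values, self.spacing_mm, self.origin_mm, unit or self.unit)


class StructureSet:
    """Named binary masks co-registered to a reference :class:`VoxelVolume`.

    Each mask carries a role (PTV/CTV/OAR/BODY/LANDMARK) and, for PTV-role
    structures, a prescription dose in Gy.
    """

    def __init__(self, reference: VoxelVolume):
        self.reference = reference
        self.masks: dict[str, np.ndarray] = {}
        self.roles: dict[str, Role] = {}
        self.rx_gy: dict[str, float] = {}

    def add(self, name: str, mask: np.ndarray, role: Role, rx_gy: float | None = None) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.reference.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} does not match reference "
                f"grid {self.reference.shape}"
            )
        self.masks[name] = mask
        self.roles[name] = Role(role)
        if rx_gy is not None:
            self.rx_gy[name] = float(rx_gy)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def names_with_role(self, role: Role) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    @property
    def body(self) -> np.ndarray:
        names = self.names_with_role(Role.BODY)
        if not names:
            raise KeyError("structure set has no BODY-role mask")
        return self.masks[names[0]]

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.reference.voxel_volume_cc

    def centroid_mm(self, name: str) -> np.ndarray:
        """Unweighted mean of mask voxel centres, in patient mm."""
        idx = np.argwhere(self.masks[name])
        if idx.size == 0:
            raise ValueError(f"structure {name!r} is empty")
        return self.reference.index_to_world(idx.mean(axis=0))

    def validate_standard(self) -> None:
        """Check the ten standard structures are present and non-empty."""
        missing = [n for n in STANDARD_STRUCTURES if n not in self.masks]
        if missing:
            raise ValueError(f"missing standard structures: {missing}")
        empty = [n for n in STANDARD_STRUCTURES if not self.masks[n].any()]
        if empty:
            raise ValueError(f"standard structures with zero volume: {empty}")
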