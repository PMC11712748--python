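"""Synthetic bilateral head-and-neck phantoms.

Generates a CT-like HU volume plus the ten modeled structures (primary PTV,
primary CTV, brainstem, cord+5 mm, left/right parotid, oral cavity, larynx,
pharynx, mandible) and lung/shoulder landmark masks, on a regular voxel
grid.  Solids are unions of ellipsoids, cylinders and boxes so every
structure has an analytic reference volume; geometry (PTV extent, parotid
position, PTV-parotid overlap, left/right asymmetry) is controlled through
:class:`PhantomSpec`.

The default spec emulates a bilateral neck target prescribed 44 Gy with an
optional sequential-boost target at 70 Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volumes import Role, StructureSet, VoxelVolume

__all__ = ["PhantomSpec", "generate_phantom", "analytic_volumes_cc"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head-and-neck geometry.

    All lengths in mm.  ``overlap_fraction`` is the target fraction of each
    parotid's volume inside the primary PTV (in [0, 0.5]); when
    ``parotid_offset_mm`` is given explicitly it takes precedence and no
    overlap solving is done.  ``asymmetry`` scales the left parotid's
    half-axes relative to the right (1.0 = mirror symmetric).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    ptv_extent_mm: tuple[float, float, float] = (96.0, 64.0, 90.0)  # full extents x/y/z
    ptv_center_mm: tuple[float, float, float] = (0.0, 5.0, 150.0)
    ctv_margin_mm: float = 5.0
    boost_present: bool = False
    boost_offset_mm: tuple[float, float, float] = (15.0, 0.0, 0.0)
    boost_rx_gy: float = 70.0
    parotid_offset_mm: float | None = None
    parotid_half_axes_mm: tuple[float, float, float] = (12.0, 20.0, 24.0)
    overlap_fraction: float = 0.1
    asymmetry: float = 1.0
    jitter_mm: float = 0.0
    seed: int = 0
    rx_gy: float = 44.0
    rx_levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if any(e <= 0 for e in self.ptv_extent_mm):
            raise ValueError("ptv_extent_mm must be positive")
        if not (0.0 <= self.overlap_fraction <= 0.5):
            raise ValueError("overlap_fraction must lie in [0, 0.5]")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")


# HU per tissue class (mean, SD of Gaussian noise).
_HU = {
    "air": (-1000.0, 0.0),
    "soft": (40.0, 8.0),
    "bone": (700.0, 60.0),
    "lung": (-700.0, 30.0),
}

_SHOULDER_TOP_Z = 70.0  # slab below this z holds shoulders/lung apices


def _grids(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    # x/y centred on the midline, z starting at 0 (inferior edge of scan)
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = np.arange(nz) * sz
    origin = (float(x[0]), float(y[0]), 0.0)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    return X, Y, Z, origin


def _ellipsoid(X, Y, Z, center, half_axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = half_axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _vertical_cylinder(X, Y, Z, center_xy, radius, z_lo, z_hi) -> np.ndarray:
    cx, cy = center_xy
    # half-open z interval so lattice-aligned bounds count (z_hi - z_lo) of height
    return ((X - cx) ** 2 + (Y - cy) ** 2 <= radius**2) & (Z >= z_lo) & (Z < z_hi)


def _body_mask(spec: PhantomSpec, X, Y, Z) -> np.ndarray:
    neck = ((X / 80.0) ** 2 + (Y / 65.0) ** 2 <= 1.0) & (Z >= _SHOULDER_TOP_Z)
    shoulders = ((X / 112.0) ** 2 + (Y / 70.0) ** 2 <= 1.0) & (Z < _SHOULDER_TOP_Z)
    return neck | shoulders


def _ptv_solid(spec: PhantomSpec, X, Y, Z, shrink_mm: float = 0.0) -> np.ndarray:
    half = tuple(max(e / 2.0 - shrink_mm, 1.0) for e in spec.ptv_extent_mm)
    return _ellipsoid(X, Y, Z, spec.ptv_center_mm, half)


def _parotid_solid(spec: PhantomSpec, X, Y, Z, side: str, offset: float) -> np.ndarray:
    ax, ay, az = spec.parotid_half_axes_mm
    scale = spec.asymmetry if side == "l" else 1.0
    half = (ax * scale, ay * scale, az * scale)
    sign = 1.0 if side == "l" else -1.0  # +x is patient-left
    cx, cy, cz = spec.ptv_center_mm
    return _ellipsoid(X, Y, Z, (sign * offset, 10.0, cz + 15.0), half)


def _solve_parotid_offset(spec: PhantomSpec, X, Y, Z, side: str) -> float:
    """Find the lateral parotid offset achieving the requested PTV overlap.

    Bisection on the offset, counting parotid voxels inside the PTV solid.
    Zero overlap places the parotid with a 3 mm gap from the PTV surface.
    """
    ptv_half_x = spec.ptv_extent_mm[0] / 2.0
    par_half_x = spec.parotid_half_axes_mm[0] * (spec.asymmetry if side == "l" else 1.0)
    if spec.overlap_fraction == 0.0:
        return ptv_half_x + par_half_x + 3.0

    ptv = _ptv_solid(spec, X, Y, Z)

    def overlap_at(offset: float) -> float:
        par = _parotid_solid(spec, X, Y, Z, side, offset)
        n = par.sum()
        return float((par & ptv).sum()) / max(int(n), 1)

    lo, hi = ptv_half_x - par_half_x, ptv_half_x + par_half_x + 3.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if overlap_at(mid) > spec.overlap_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _jitter(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Optional Gaussian boundary jitter: noisy threshold on the mask edge."""
    if spec.jitter_mm <= 0:
        return mask
    from scipy import ndimage

    sigma_vox = spec.jitter_mm / float(np.mean(spec.spacing_mm))
    soft = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    noise = rng.normal(0.0, 0.05, size=mask.shape)
    return (soft + noise) >= 0.5


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, StructureSet]:
    """Build the HU volume and 10-structure set (plus landmarks) for ``spec``.

    Deterministic for a given spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z, origin = _grids(spec)

    body = _body_mask(spec, X, Y, Z)

    ptv = _ptv_solid(spec, X, Y, Z)
    ctv = _ptv_solid(spec, X, Y, Z, shrink_mm=spec.ctv_margin_mm)

    cx, cy, cz = spec.ptv_center_mm
    brainstem = _ellipsoid(X, Y, Z, (0.0, 25.0, cz + 65.0), (10.0, 10.0, 22.0))
    cord = _vertical_cylinder(X, Y, Z, (0.0, 35.0), 12.0, _SHOULDER_TOP_Z, cz + 60.0)
    oral_cavity = _ellipsoid(X, Y, Z, (0.0, -35.0, cz + 10.0), (28.0, 18.0, 25.0))
    larynx = _ellipsoid(X, Y, Z, (0.0, -30.0, cz - 45.0), (15.0, 15.0, 25.0))
    pharynx = _ellipsoid(X, Y, Z, (0.0, 12.0, cz - 20.0), (12.0, 14.0, 45.0))

    # Mandible: anterior half of a vertical cylindrical shell (bone).
    r2 = (X - 0.0) ** 2 + (Y + 20.0) ** 2
    mandible = (
        (r2 >= 30.0**2) & (r2 <= 40.0**2) & (Y <= -20.0)
        & (Z >= cz + 5.0) & (Z < cz + 30.0)
    )

    if spec.parotid_offset_mm is not None:
        off_l = off_r = float(spec.parotid_offset_mm)
    else:
        off_l = _solve_parotid_offset(spec, X, Y, Z, "l")
        off_r = _solve_parotid_offset(spec, X, Y, Z, "r")
    parotid_l = _parotid_solid(spec, X, Y, Z, "l", off_l)
    parotid_r = _parotid_solid(spec, X, Y, Z, "r", off_r)

    lungs = _ellipsoid(X, Y, Z, (45.0, 5.0, 30.0), (30.0, 35.0, 32.0)) | _ellipsoid(
        X, Y, Z, (-45.0, 5.0, 30.0), (30.0, 35.0, 32.0)
    )
    shoulders = (
        (np.abs(X) >= 60.0) & (np.abs(X) <= 105.0)
        & (Y >= -35.0) & (Y <= 45.0)
        & (Z >= 5.0) & (Z <= 65.0)
    )

    # Vertebral bone: annulus around the cord canal (tissue only, no mask).
    rc2 = X**2 + (Y - 35.0) ** 2
    vertebra = (rc2 >= 14.0**2) & (rc2 <= 24.0**2) & (Z >= _SHOULDER_TOP_Z)

    masks: dict[str, np.ndarray] = {
        "ptv": ptv,
        "ctv": ctv,
        "brainstem": brainstem,
        "cord_plus_5mm": cord,
        "parotid_l": parotid_l,
        "parotid_r": parotid_r,
        "oral_cavity": oral_cavity,
        "larynx": larynx,
        "pharynx": pharynx,
        "mandible": mandible,
    }
    landmark_masks = {"lungs": lungs & body, "shoulders": shoulders & body}

    if spec.jitter_mm > 0:
        masks = {n: _jitter(m, spec, rng) for n, m in masks.items()}
        masks["ctv"] = masks["ctv"] & masks["ptv"]  # containment survives jitter
    masks = {n: m & body for n, m in masks.items()}

    # HU assignment per tissue class with seeded Gaussian noise.
    hu = np.full(spec.grid_shape, _HU["air"][0], dtype=np.float64)
    soft_mu, soft_sd = _HU["soft"]
    hu[body] = soft_mu + soft_sd * rng.standard_normal(int(body.sum()))
    lung_region = landmark_masks["lungs"]
    lung_mu, lung_sd = _HU["lung"]
    hu[lung_region] = lung_mu + lung_sd * rng.standard_normal(int(lung_region.sum()))
    bone_region = (vertebra | mandible) & body
    bone_mu, bone_sd = _HU["bone"]
    hu[bone_region] = bone_mu + bone_sd * rng.standard_normal(int(bone_region.sum()))

    volume = VoxelVolume(hu, spec.spacing_mm, origin, unit="HU")

    structures = StructureSet(volume)
    structures.add("body", body, Role.BODY)
    rx = dict(spec.rx_levels)
    rx.setdefault("ptv", spec.rx_gy)
    structures.add("ptv", masks["ptv"], Role.PTV, rx_gy=rx["ptv"])
    structures.add("ctv", masks["ctv"], Role.CTV)
    for name in (
        "brainstem", "cord_plus_5mm", "parotid_l", "parotid_r",
        "oral_cavity", "larynx", "pharynx", "mandible",
    ):
        structures.add(name, masks[name], Role.OAR)
    for name, mask in landmark_masks.items():
        structures.add(name, mask, Role.LANDMARK)

    if spec.boost_present:
        boost_rx = rx.get("ptv_boost", spec.boost_rx_gy)
        if boost_rx == rx["ptv"]:
            raise ValueError(
                "boost and primary PTV share the same prescription: the "
                "highest-dose PTV is ambiguous"
            )
        boost_center = tuple(np.asarray(spec.ptv_center_mm) + np.asarray(spec.boost_offset_mm))
        boost = _ellipsoid(X, Y, Z, boost_center, (20.0, 16.0, 20.0)) & body
        structures.add("ptv_boost", boost, Role.PTV, rx_gy=boost_rx)

    return volume, structures


def analytic_volumes_cc(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form volumes (cc) of the generating solids, pre body-clipping.

    Reference values for the voxel-counting volume invariant; structures
    whose solids the body may clip (landmarks) are omitted.
    """
    def ell(a, b, c):
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    hx, hy, hz = (e / 2.0 for e in spec.ptv_extent_mm)
    m = spec.ctv_margin_mm
    pax, pay, paz = spec.parotid_half_axes_mm
    out = {
        "ptv": ell(hx, hy, hz),
        "ctv": ell(hx - m, hy - m, hz - m),
        "brainstem": ell(10.0, 10.0, 22.0),
        "cord_plus_5mm": math.pi * 12.0**2 * (spec.ptv_center_mm[2] + 60.0 - _SHOULDER_TOP_Z) / 1000.0,
        "parotid_l": ell(pax, pay, paz) * spec.asymmetry**3,
        "parotid_r": ell(pax, pay, paz),
        "oral_cavity": ell(28.0, 18.0, 25.0),
        "larynx": ell(15.0, 15.0, 25.0),
        "pharynx": ell(12.0, 14.0, 45.0),
        "mandible": 0.5 * math.pi * (40.0**2 - 30.0**2) * 25.0 / 1000.0,
    }
    return out
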