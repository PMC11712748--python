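"""Beam's-eye-view anatomical projections on the fluence-map grid.

Two projection kinds supply the 12-channel per-beam anatomical input:

* *intra-structure* projections integrate CT-derived density only over ray
  voxels inside a structure mask (the CT is truncated outside the mask);
* *interface* projections integrate density from the ray's first entry into
  the BODY surface to its last exit from the structure's surface (zero
  where the ray misses the structure).

Interface projections are built for all 10 modeled structures and intra
projections for PTV and CTV.  Each channel lives on the 128 x 128 /
2.5 mm fluence grid centred on the beam axis in the isocenter plane and is
max-normalised to [0, 1].

Rays integrate relative electron density obtained from HU through a
piecewise-linear lookup; summing (a true line integral, mm units) is the
default aggregation, with a mean-along-chord alternative exposed because
any monotone scaling is an acceptable model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    FLUENCE_PIXEL_MM,
    FLUENCE_SHAPE,
    BeamTemplate,
    beam_unit_vectors,
    fluence_pixel_coords,
    source_position,
)
from .raytrace import BeamTraversal
from .volumes import STANDARD_STRUCTURES, StructureSet, VoxelVolume

__all__ = [
    "ProjectionStack",
    "hu_to_density",
    "beam_traversal",
    "intra_projection",
    "interface_projection",
    "build_stack",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"interface:{name}" for name in STANDARD_STRUCTURES
) + ("intra:ptv", "intra:ctv")

# HU -> relative electron density control points (piecewise linear).
_HU_TABLE = np.array([-1000.0, 0.0, 1000.0, 3000.0])
_RHO_TABLE = np.array([0.0, 1.0, 1.55, 2.5])


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Relative electron density from HU via a piecewise-linear table."""
    return np.interp(hu, _HU_TABLE, _RHO_TABLE)


@dataclass
class ProjectionStack:
    """Per-beam 12-channel anatomical input on the fluence grid."""

    channels: dict[str, np.ndarray]
    beam_index: int
    pixel_mm: float = FLUENCE_PIXEL_MM

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNEL_NAMES):
            raise ValueError(
                f"stack must contain exactly the channels {sorted(CHANNEL_NAMES)}"
            )
        for name, ch in self.channels.items():
            if ch.shape != FLUENCE_SHAPE:
                raise ValueError(f"channel {name!r} is {ch.shape}, expected {FLUENCE_SHAPE}")
            if not np.all(np.isfinite(ch)) or (ch < 0).any():
                raise ValueError(f"channel {name!r} has negative or non-finite values")

    def array(self) -> np.ndarray:
        """(12, 128, 128) array in canonical channel order."""
        return np.stack([self.channels[n] for n in CHANNEL_NAMES])


def _pixel_positions(template: BeamTemplate, beam: int,
                     shape=FLUENCE_SHAPE, pixel_mm: float = FLUENCE_PIXEL_MM):
    iso = np.asarray(template.isocenter_mm, float)
    u, v, _ = beam_unit_vectors(template.gantry_deg[beam])
    ug, vg = fluence_pixel_coords(shape, pixel_mm)
    UG, VG = np.meshgrid(ug, vg, indexing="ij")
    return iso + UG.reshape(-1, 1) * u + VG.reshape(-1, 1) * v


def beam_traversal(ct: VoxelVolume, template: BeamTemplate, beam: int,
                   shape=FLUENCE_SHAPE, pixel_mm: float = FLUENCE_PIXEL_MM) -> BeamTraversal:
    """Traversal of all fluence-pixel rays of one beam (cacheable)."""
    src = source_position(template.isocenter_mm, template.gantry_deg[beam], template.sad_mm)
    pixels = _pixel_positions(template, beam, shape, pixel_mm)
    return BeamTraversal.compute(ct, src, pixels)


def _density(ct: VoxelVolume) -> np.ndarray:
    return hu_to_density(ct.values)


def intra_projection(ct: VoxelVolume, mask: np.ndarray, template: BeamTemplate,
                     beam: int, *, traversal: BeamTraversal | None = None,
                     aggregate: str = "sum",
                     shape=FLUENCE_SHAPE, pixel_mm: float = FLUENCE_PIXEL_MM) -> np.ndarray:
    """Line integral of density restricted to voxels inside ``mask``."""
    tr = traversal or beam_traversal(ct, template, beam, shape, pixel_mm)
    field = _density(ct) * mask
    out = tr.integrate(field)
    if aggregate == "mean":
        inside = tr.gather(mask.astype(np.float64)) * tr.lengths
        chord = inside.sum(axis=1)
        out = np.divide(out, chord, out=np.zeros_like(out), where=chord > 0)
    elif aggregate != "sum":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return out.reshape(shape)


def interface_projection(ct: VoxelVolume, structure_mask: np.ndarray,
                         body_mask: np.ndarray, template: BeamTemplate, beam: int,
                         *, traversal: BeamTraversal | None = None,
                         aggregate: str = "sum",
                         shape=FLUENCE_SHAPE, pixel_mm: float = FLUENCE_PIXEL_MM) -> np.ndarray:
    """Density integral from body entry to the structure's last exit.

    Zero for rays that miss the structure (or the body).
    """
    tr = traversal or beam_traversal(ct, template, beam, shape, pixel_mm)
    body_hit = tr.gather(body_mask) & tr.valid
    struct_hit = tr.gather(structure_mask) & tr.valid

    t_entry = np.where(body_hit, tr.t_start, np.inf).min(axis=1)
    t_exit = np.where(struct_hit, tr.t_end, -np.inf).max(axis=1)
    window = (
        tr.valid
        & (0.5 * (tr.t_start + tr.t_end) >= t_entry[:, None])
        & (0.5 * (tr.t_start + tr.t_end) <= t_exit[:, None])
    )
    out = tr.integrate(_density(ct), weight=window)
    if aggregate == "mean":
        chord = (tr.lengths * window).sum(axis=1)
        out = np.divide(out, chord, out=np.zeros_like(out), where=chord > 0)
    elif aggregate != "sum":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return out.reshape(shape)


def build_stack(ct: VoxelVolume, structures: StructureSet, template: BeamTemplate,
                beam: int, *, traversal: BeamTraversal | None = None,
                aggregate: str = "sum") -> ProjectionStack:
    """Assemble the normalised 12-channel stack for one beam."""
    structures.validate_standard()
    body = structures.body
    tr = traversal or beam_traversal(ct, template, beam)

    channels: dict[str, np.ndarray] = {}
    if aggregate == "sum":
        # fast path: share the per-segment density integrand across channels
        dens_seg = tr.gather(_density(ct)) * tr.lengths
        t_mid = 0.5 * (tr.t_start + tr.t_end)
        body_hit = tr.gather(body) & tr.valid
        t_entry = np.where(body_hit, tr.t_start, np.inf).min(axis=1)
        for name in STANDARD_STRUCTURES:
            hit = tr.gather(structures[name]) & tr.valid
            t_exit = np.where(hit, tr.t_end, -np.inf).max(axis=1)
            window = tr.valid & (t_mid >= t_entry[:, None]) & (t_mid <= t_exit[:, None])
            channels[f"interface:{name}"] = (dens_seg * window).sum(axis=1).reshape(FLUENCE_SHAPE)
        for name in ("ptv", "ctv"):
            inside = tr.gather(structures[name]) & tr.valid
            channels[f"intra:{name}"] = (dens_seg * inside).sum(axis=1).reshape(FLUENCE_SHAPE)
    else:
        for name in STANDARD_STRUCTURES:
            channels[f"interface:{name}"] = interface_projection(
                ct, structures[name], body, template, beam,
                traversal=tr, aggregate=aggregate,
            )
        for name in ("ptv", "ctv"):
            channels[f"intra:{name}"] = intra_projection(
                ct, structures[name], template, beam, traversal=tr, aggregate=aggregate
            )

    for name, ch in channels.items():
        peak = ch.max()
        if peak > 0:
            channels[name] = ch / peak
    return ProjectionStack(channels=channels, beam_index=beam)
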