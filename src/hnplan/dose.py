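"""Simplified forward dose engine and prescription normalisation.

The engine maps each fluence pixel onto its divergent ray through the CT
grid and deposits, per traversed voxel segment,

    fluence * exp(-mu * radiological_depth) * (SAD / r)^2 * segment_length

where the radiological depth is the density line integral from the body
entry to the segment midpoint (reusing the projection ray tracer), r the
distance from the source and SAD the source-axis distance.  Beam deposits
are summed and blurred with a 3D Gaussian lateral-scatter kernel; dose is
zeroed outside the BODY mask expanded by a buildup margin.

This is a transparent exponential-attenuation pencil engine for desk-scale
experimentation — it makes no claim to convolution/superposition accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fluence import FluenceMap
from .geometry import BeamTemplate
from .projection import beam_traversal, hu_to_density
from .raytrace import BeamTraversal
from .volumes import StructureSet, VoxelVolume

__all__ = [
    "EngineParams",
    "compute_dose",
    "normalize_to_prescription",
    "rescale_prescription",
    "total_mu_proxy",
    "d_at_percent",
]


@dataclass(frozen=True)
class EngineParams:
    """Tunable engine constants (water-equivalent head-and-neck defaults)."""

    mu_per_mm: float = 0.005        # effective linear attenuation
    scatter_sigma_mm: float = 4.0   # lateral-scatter Gaussian
    output_per_fluence: float = 1.0 # Gy per unit fluence*mm at zero depth
    body_margin_mm: float = 10.0    # buildup margin outside BODY kept nonzero


def compute_dose(ct: VoxelVolume, structures: StructureSet, template: BeamTemplate,
                 fluences: Sequence[FluenceMap],
                 params: EngineParams = EngineParams(),
                 traversals: Sequence[BeamTraversal] | None = None) -> VoxelVolume:
    """Forward dose of all beams on the CT grid (unit Gy, relative scale)."""
    if len(fluences) != template.n_beams:
        raise ValueError(
            f"{len(fluences)} fluence maps for {template.n_beams} template beams"
        )
    density = hu_to_density(ct.values)
    nvox = int(np.prod(ct.shape))
    deposit = np.zeros(nvox, dtype=np.float64)

    for beam, fmap in enumerate(fluences):
        tr = traversals[beam] if traversals is not None else beam_traversal(
            ct, template, beam, fmap.values.shape, fmap.pixel_mm
        )
        rho = tr.gather(density) * tr.lengths            # per-segment rad. length
        raddepth = np.cumsum(rho, axis=1) - 0.5 * rho    # at segment midpoints
        t_mid = 0.5 * (tr.t_start + tr.t_end)
        r = t_mid * tr.dnorm[:, None]                    # distance from source
        r = np.where(r > 1e-6, r, np.inf)
        w = (
            fmap.values.reshape(-1, 1)
            * np.exp(-params.mu_per_mm * raddepth)
            * (template.sad_mm / r) ** 2
            * tr.lengths
        )
        w = np.where(tr.valid, w, 0.0)
        deposit += np.bincount(tr.flat_idx.ravel(), weights=w.ravel(), minlength=nvox)

    dose = deposit.reshape(ct.shape) * params.output_per_fluence
    if params.scatter_sigma_mm > 0:
        sigma_vox = [params.scatter_sigma_mm / s for s in ct.spacing_mm]
        dose = ndimage.gaussian_filter(dose, sigma=sigma_vox)

    body = structures.body
    if params.body_margin_mm > 0:
        outside_dist = ndimage.distance_transform_edt(~body, sampling=ct.spacing_mm)
        region = outside_dist <= params.body_margin_mm
    else:
        region = body
    dose = np.where(region, dose, 0.0)
    return ct.with_values(np.maximum(dose, 0.0), unit="Gy")


def d_at_percent(dose_values: np.ndarray, mask: np.ndarray, q_pct: float) -> float:
    """D_q%: minimum dose to the hottest q% of the structure (interpolated)."""
    vals = dose_values[mask]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    return float(np.percentile(vals, 100.0 - q_pct))


def normalize_to_prescription(dose: VoxelVolume, ptv_mask: np.ndarray,
                              rx_gy: float = 44.0,
                              coverage_pct: float = 95.0) -> tuple[VoxelVolume, float]:
    """Scale the plan so the prescription covers ``coverage_pct``% of the PTV.

    A single scalar maps D95%(PTV) onto ``rx_gy`` exactly (interpolated DVH
    inversion); returns the scaled dose and the scalar applied.
    """
    d_cov = d_at_percent(dose.values, ptv_mask, coverage_pct)
    if d_cov <= 0:
        raise ValueError("PTV dose is zero; cannot normalise to prescription")
    scale = rx_gy / d_cov
    return dose.with_values(dose.values * scale, unit="Gy"), float(scale)


def rescale_prescription(dose: VoxelVolume, from_gy: float = 50.0,
                         to_gy: float = 44.0) -> VoxelVolume:
    """Linear rescale between prescription levels (e.g. 50 Gy plans to 44 Gy)."""
    if from_gy <= 0:
        raise ValueError("from_gy must be positive")
    return dose.with_values(dose.values * (to_gy / from_gy), unit="Gy")


def total_mu_proxy(fluences: Sequence[FluenceMap], calibration: float = 100.0) -> float:
    """Relative delivery-effort proxy: calibration * sum of per-beam maxima.

    A stand-in for total monitor units on a relative scale; it is not a
    clinical MU computation.
    """
    return float(calibration * sum(f.values.max() for f in fluences))
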