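"""DVH computation and dosimetric plan endpoints.

Implements the cumulative dose-volume histogram, the conformity index

    CI = V_PR / V_PTV

(prescription-isodose volume, measured over BODY by convention, divided by
the PTV volume), the heterogeneity index

    HI = (D2% - D98%) / Rx

(reported x100 to match the usual clinical scale, e.g. 9.3), interpolated
D_x% / D_cc / median endpoints, and the standard per-plan endpoint row used
by the commissioning analysis.

D_q% uses linear interpolation on the sorted voxel doses (order
statistics), which is equivalent to interpolated inversion of the
cumulative DVH; D_cc converts absolute volume to a percentage of the
structure volume first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import d_at_percent, total_mu_proxy
from .volumes import StructureSet, VoxelVolume

__all__ = [
    "DVHCurve",
    "dvh",
    "conformity_index",
    "heterogeneity_index",
    "dose_at_volume",
    "median_dose",
    "endpoint_table",
    "STANDARD_ENDPOINTS",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= dose."""

    dose_gy: np.ndarray
    volume_pct: np.ndarray
    structure: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")

    def resample(self, dose_axis: np.ndarray) -> "DVHCurve":
        vol = np.interp(dose_axis, self.dose_gy, self.volume_pct, left=100.0, right=0.0)
        return DVHCurve(np.asarray(dose_axis, float), vol, self.structure)


def dvh(dose: VoxelVolume, mask: np.ndarray, bin_gy: float = 0.1,
        structure: str = "", max_gy: float | None = None) -> DVHCurve:
    """Voxel-counted cumulative DVH on a uniform dose grid."""
    vals = dose.values[mask]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    top = max_gy if max_gy is not None else float(vals.max()) + bin_gy
    edges = np.arange(0.0, top + bin_gy, bin_gy)
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    at_least = counts[::-1].cumsum()[::-1]  # voxels with dose >= edge
    return DVHCurve(edges, 100.0 * at_least / vals.size, structure)


def conformity_index(dose: VoxelVolume, ptv_mask: np.ndarray, rx_gy: float,
                     body_mask: np.ndarray | None = None) -> float:
    """CI = prescription-isodose volume / PTV volume.

    The isodose volume is counted over BODY when a body mask is given
    (standard convention), otherwise over the whole grid.
    """
    n_ptv = int(ptv_mask.sum())
    if n_ptv == 0:
        raise ValueError("empty PTV mask")
    iso = dose.values >= rx_gy
    if body_mask is not None:
        iso = iso & body_mask
    return float(iso.sum()) / n_ptv


def heterogeneity_index(dose: VoxelVolume, ptv_mask: np.ndarray, rx_gy: float,
                        scale100: bool = True) -> float:
    """HI = (D2% - D98%) / Rx; x100 by default to match clinical reporting."""
    d2 = d_at_percent(dose.values, ptv_mask, 2.0)
    d98 = d_at_percent(dose.values, ptv_mask, 98.0)
    hi = (d2 - d98) / rx_gy
    return float(hi * 100.0) if scale100 else float(hi)


def dose_at_volume(dose: VoxelVolume, mask: np.ndarray, *, pct: float | None = None,
                   cc: float | None = None) -> float:
    """D_x% or D_xcc of a structure (minimum dose to its hottest x% / x cc)."""
    if (pct is None) == (cc is None):
        raise ValueError("give exactly one of pct= or cc=")
    if cc is not None:
        vol_cc = float(mask.sum()) * dose.voxel_volume_cc
        if cc > vol_cc:
            raise ValueError(f"{cc} cc exceeds the structure volume {vol_cc:.2f} cc")
        pct = 100.0 * cc / vol_cc
    if not (0.0 < pct <= 100.0):
        raise ValueError(f"volume percentage {pct} out of (0, 100]")
    return d_at_percent(dose.values, mask, pct)


def median_dose(dose: VoxelVolume, mask: np.ndarray) -> float:
    """D50%: median structure dose."""
    return d_at_percent(dose.values, mask, 50.0)


#: Endpoint row set of the commissioning comparison (one value per plan).
STANDARD_ENDPOINTS: tuple[str, ...] = (
    "ci",
    "hi",
    "body_d1cc_gy",
    "brainstem_d0p1cc_gy",
    "cord_plus_5mm_d0p1cc_gy",
    "parotid_l_dmedian_gy",
    "parotid_r_dmedian_gy",
    "oral_cavity_dmedian_gy",
    "larynx_dmedian_gy",
    "pharynx_dmedian_gy",
    "mandible_d1cc_gy",
    "total_mu",
)


def endpoint_table(dose: VoxelVolume, structures: StructureSet, rx_gy: float = 44.0,
                   fluences=None, label: str = "") -> pd.Series:
    """The standard endpoint row for one plan (CI, HI, OAR doses, MU proxy)."""
    ptv = structures["ptv"]
    body = structures.body
    row = {
        "ci": conformity_index(dose, ptv, rx_gy, body_mask=body),
        "hi": heterogeneity_index(dose, ptv, rx_gy),
        "body_d1cc_gy": dose_at_volume(dose, body, cc=1.0),
        "brainstem_d0p1cc_gy": dose_at_volume(dose, structures["brainstem"], cc=0.1),
        "cord_plus_5mm_d0p1cc_gy": dose_at_volume(dose, structures["cord_plus_5mm"], cc=0.1),
        "parotid_l_dmedian_gy": median_dose(dose, structures["parotid_l"]),
        "parotid_r_dmedian_gy": median_dose(dose, structures["parotid_r"]),
        "oral_cavity_dmedian_gy": median_dose(dose, structures["oral_cavity"]),
        "larynx_dmedian_gy": median_dose(dose, structures["larynx"]),
        "pharynx_dmedian_gy": median_dose(dose, structures["pharynx"]),
        "mandible_d1cc_gy": dose_at_volume(dose, structures["mandible"], cc=1.0),
        "total_mu": total_mu_proxy(fluences) if fluences is not None else np.nan,
    }
    return pd.Series(row, name=label or None)
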