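"""Gamma-index dose comparison and per-field passing-rate reports.

For each evaluated point above the low-dose threshold,

    gamma = min over reference neighborhood of
            sqrt((dose_diff / dose_crit)^2 + (distance / dist_crit)^2)

with the reference sampled on a sub-pixel fine grid (linear interpolation)
within a search radius of ``search_factor`` times the distance criterion.
The passing rate (GPR) is the percentage of evaluated points with
gamma <= 1.

Defaults follow the common portal-dosimetry setup: global normalisation to
the reference maximum, 10% low-dose threshold (on the evaluated grid),
search radius 3x the distance criterion and a search step of one tenth of
it.  All of these are parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["GammaResult", "gamma_index", "field_pass_report"]

_PASS_TOL = 1e-6  # gamma <= 1 is inclusive at float precision


@dataclass
class GammaResult:
    gamma: np.ndarray          # nan where below threshold
    gpr_pct: float
    dose_pct: float
    dist_mm: float
    threshold_pct: float
    mode: str

    @property
    def n_evaluated(self) -> int:
        return int(np.isfinite(self.gamma).sum())


def gamma_index(reference: np.ndarray, evaluated: np.ndarray,
                spacing_mm: Sequence[float] | float,
                dose_pct: float = 3.0, dist_mm: float = 2.0,
                threshold_pct: float = 10.0, mode: str = "global",
                search_factor: float = 3.0,
                step_mm: float | None = None) -> GammaResult:
    """Gamma map and passing rate between two co-registered dose grids.

    ``reference`` and ``evaluated`` share shape and ``spacing_mm`` (scalar
    or per-axis); works for 2D planes and 3D grids.  The low-dose threshold
    is applied to the evaluated grid against the reference maximum.
    """
    reference = np.asarray(reference, float)
    evaluated = np.asarray(evaluated, float)
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated grids differ in shape")
    ndim = reference.ndim
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing_mm, float)), (ndim,))
    if np.any(spacing <= 0):
        raise ValueError("grid spacing must be positive and present")
    if dose_pct <= 0 or dist_mm <= 0:
        raise ValueError("gamma criteria must be positive")
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")

    ref_max = reference.max()
    if ref_max <= 0:
        raise ValueError("reference grid has no positive dose")
    threshold = threshold_pct / 100.0 * ref_max
    active = evaluated >= threshold
    if not active.any():
        raise ValueError("all evaluated points fall below the dose threshold")

    step = step_mm if step_mm is not None else dist_mm / 10.0
    radius = search_factor * dist_mm
    # integer construction so the zero displacement is sampled exactly
    k = int(np.floor(radius / step + 1e-9))
    offsets_1d = np.arange(-k, k + 1) * step
    global_crit = dose_pct / 100.0 * ref_max

    base_idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in reference.shape],
                    indexing="ij")
    )  # (ndim, *shape)

    gamma_sq = np.full(reference.shape, np.inf)
    for shift in itertools.product(offsets_1d, repeat=ndim):
        r2 = float(np.dot(shift, shift))
        if r2 > radius**2 + 1e-9:
            continue
        coords = base_idx + (np.asarray(shift) / spacing)[(...,) + (None,) * ndim]
        ref_s = ndimage.map_coordinates(reference, coords.reshape(ndim, -1),
                                        order=1, mode="constant",
                                        cval=np.nan).reshape(reference.shape)
        if mode == "global":
            crit = global_crit
        else:
            crit = dose_pct / 100.0 * ref_s
        with np.errstate(invalid="ignore", divide="ignore"):
            cand = ((evaluated - ref_s) / crit) ** 2 + r2 / dist_mm**2
        cand = np.where(np.isfinite(cand), cand, np.inf)
        np.minimum(gamma_sq, cand, out=gamma_sq)

    gamma = np.sqrt(gamma_sq)
    gamma = np.where(active, gamma, np.nan)
    passing = gamma[active] <= 1.0 + _PASS_TOL
    gpr = 100.0 * passing.mean()
    return GammaResult(gamma, float(gpr), dose_pct, dist_mm, threshold_pct, mode)


def field_pass_report(fields: Sequence[tuple[str, np.ndarray, np.ndarray]],
                      spacing_mm, pass_pct: float = 95.0,
                      primary=(3.0, 2.0), fallback=(2.0, 4.0),
                      **gamma_kwargs) -> dict:
    """Two-tier per-field gamma QA summary.

    Each field is ``(name, reference, evaluated)``.  Fields failing the
    primary criteria (GPR < ``pass_pct``) are re-evaluated at the fallback
    criteria; the summary reports per-field GPRs, pass flags and the
    mean +/- SD GPR at the primary criteria.
    """
    rows = []
    for name, ref, ev in fields:
        res = gamma_index(ref, ev, spacing_mm, dose_pct=primary[0],
                          dist_mm=primary[1], **gamma_kwargs)
        row = {
            "field": name,
            "gpr_pct": res.gpr_pct,
            "pass_primary": res.gpr_pct >= pass_pct,
            "gpr_fallback_pct": None,
            "pass_fallback": None,
        }
        if not row["pass_primary"]:
            res_fb = gamma_index(ref, ev, spacing_mm, dose_pct=fallback[0],
                                 dist_mm=fallback[1], **gamma_kwargs)
            row["gpr_fallback_pct"] = res_fb.gpr_pct
            row["pass_fallback"] = res_fb.gpr_pct >= pass_pct
        rows.append(row)
    gprs = np.array([r["gpr_pct"] for r in rows])
    return {
        "fields": rows,
        "mean_gpr_pct": float(gprs.mean()),
        "sd_gpr_pct": float(gprs.std(ddof=1)) if len(gprs) > 1 else 0.0,
        "n_fail_primary": int(sum(not r["pass_primary"] for r in rows)),
        "criteria_primary": tuple(primary),
        "criteria_fallback": tuple(fallback),
        "pass_pct": pass_pct,
    }
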