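"""Commissioning analysis: case grouping, paired statistics and DVH bands.

Commissioning compares, per case, a clinical reference plan against the
automated plans.  Cases are grouped by the clinical plan's parotid
tradeoff (bilateral / left-spared / right-spared); within each group three
paired two-sided Wilcoxon signed-rank comparisons are run per endpoint:

* p1: clinical vs the PTV-priority automated plan (BP/LP/RP),
* p2: clinical vs the OAR-priority automated plan (BO/LO/RO),
* p3: PTV-priority vs OAR-priority automated plans,

with Bonferroni correction over the endpoint family at alpha = 0.05.

The signed-rank test uses the exact sign-flip distribution (all 2^n sign
assignments, tie-aware via average ranks) for n <= 12 pairs and the normal
approximation with tie and continuity corrections for larger n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import DVHCurve, STANDARD_ENDPOINTS

__all__ = [
    "CommissionCase",
    "assign_group",
    "paired_wilcoxon",
    "bonferroni",
    "dvh_bands",
    "build_report",
    "synthetic_commissioning_cases",
    "GROUP_PROFILES",
]

#: Which automated profiles are compared against each clinical group.
GROUP_PROFILES = {
    "bilateral": ("BP", "BO"),
    "left": ("LP", "LO"),
    "right": ("RP", "RO"),
}


@dataclass
class CommissionCase:
    """One commissioning case: clinical endpoints + per-profile AI endpoints."""

    case_id: str
    clinical: pd.Series
    ai: dict[str, pd.Series]
    dvhs: dict[str, dict[str, DVHCurve]] = field(default_factory=dict)  # plan -> structure -> curve
    group: str | None = None


def assign_group(clinical_endpoints: Mapping[str, float], tau_gy: float = 3.0) -> str:
    """Parotid-tradeoff group of a clinical plan.

    Similar left/right parotid median doses (|difference| <= tau) mean the
    plan spared both parotids ('bilateral'); otherwise the lower-dose side
    names the group.
    """
    try:
        left = float(clinical_endpoints["parotid_l_dmedian_gy"])
        right = float(clinical_endpoints["parotid_r_dmedian_gy"])
    except KeyError as e:
        raise ValueError(f"missing parotid median dose: {e}") from None
    if abs(left - right) <= tau_gy:
        return "bilateral"
    return "left" if left < right else "right"


def _exact_signflip_p(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Equivalent to summing over all 2^n equiprobable sign flips; implemented
    as a subset-sum distribution over (doubled, hence integer even with
    midrank ties) ranks.
    """
    ranks = stats.rankdata(np.abs(diffs))
    r2 = np.round(2 * ranks).astype(int)
    total = r2.sum()
    # counts[w] = number of sign assignments with doubled W+ == w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w_obs = int(np.round(r2[diffs > 0].sum()))
    cdf = counts[: w_obs + 1].sum()
    sf = counts[w_obs:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    exact_max_n: int = 12) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; at least 5 informative pairs are
    required.  Exact enumeration for small n, normal approximation with
    tie/continuity correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if diffs.size < 5:
        raise ValueError(
            f"only {diffs.size} nonzero paired differences; need >= 5"
        )
    if diffs.size <= exact_max_n:
        return _exact_signflip_p(diffs)
    res = stats.wilcoxon(diffs, zero_method="wilcox", correction=True,
                         alternative="two-sided", method="approx")
    return float(res.pvalue)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05,
               m: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-corrected significance flags and adjusted p-values.

    The family size ``m`` defaults to the number of p-values (one family
    per comparison column of the endpoint table); significant iff
    p <= alpha / m, equivalently min(1, p*m) <= alpha.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = m if m is not None else p.size
    adjusted = np.minimum(1.0, p * m_eff)
    return p <= alpha / m_eff, adjusted


def dvh_bands(curves: Sequence[DVHCurve], dose_axis: np.ndarray | None = None,
              percentiles: tuple[float, float] = (25.0, 75.0)) -> pd.DataFrame:
    """Pointwise median and percentile band of DVHs across cases.

    Curves are resampled to a common dose axis first; statistics are taken
    over percentage volume at each dose grid point.
    """
    if not curves:
        raise ValueError("no DVH curves given")
    if dose_axis is None:
        top = max(float(c.dose_gy.max()) for c in curves)
        dose_axis = np.arange(0.0, top + 0.5, 0.5)
    vols = np.stack([c.resample(dose_axis).volume_pct for c in curves])
    lo, hi = percentiles
    return pd.DataFrame({
        "dose_gy": dose_axis,
        "median_pct": np.median(vols, axis=0),
        f"p{lo:g}_pct": np.percentile(vols, lo, axis=0),
        f"p{hi:g}_pct": np.percentile(vols, hi, axis=0),
    })


def _median_iqr(values: np.ndarray) -> str:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    return f"{med:.4g} ({q3 - q1:.3g})"


def build_report(cases: Sequence[CommissionCase], alpha: float = 0.05,
                 tau_gy: float = 3.0, m: int | None = None,
                 endpoints: Sequence[str] = STANDARD_ENDPOINTS) -> dict[str, pd.DataFrame]:
    """Per-group endpoint summary with p1/p2/p3 and Bonferroni flags.

    Returns one DataFrame per group: median (IQR) per plan type, raw
    p-values and corrected significance flags.  The Bonferroni family is
    the endpoint column (size ``m``, default: number of endpoints).
    """
    for case in cases:
        if case.group is None:
            case.group = assign_group(case.clinical, tau_gy)

    report: dict[str, pd.DataFrame] = {}
    for group, (prof_p, prof_o) in GROUP_PROFILES.items():
        members = [c for c in cases if c.group == group]
        if not members:
            continue
        clin = pd.DataFrame([c.clinical for c in members])
        ai_p = pd.DataFrame([c.ai[prof_p] for c in members])
        ai_o = pd.DataFrame([c.ai[prof_o] for c in members])

        rows = []
        for ep in endpoints:
            c, p_, o_ = clin[ep].to_numpy(), ai_p[ep].to_numpy(), ai_o[ep].to_numpy()
            rows.append({
                "endpoint": ep,
                "clinical": _median_iqr(c),
                f"ai_{prof_p}": _median_iqr(p_),
                f"ai_{prof_o}": _median_iqr(o_),
                "p1": paired_wilcoxon(c, p_),
                "p2": paired_wilcoxon(c, o_),
                "p3": paired_wilcoxon(p_, o_),
            })
        table = pd.DataFrame(rows).set_index("endpoint")
        m_eff = m if m is not None else len(endpoints)
        for col in ("p1", "p2", "p3"):
            flags, _ = bonferroni(table[col].to_numpy(), alpha=alpha, m=m_eff)
            table[f"{col}_significant"] = flags
        table.attrs["n_cases"] = len(members)
        table.attrs["bonferroni_m"] = m_eff
        table.attrs["alpha"] = alpha
        report[group] = table
    return report


def synthetic_commissioning_cases(
    n_cases: int = 18,
    group: str = "bilateral",
    shifts: Mapping[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    endpoints: Sequence[str] = STANDARD_ENDPOINTS,
) -> list[CommissionCase]:
    """Synthetic paired endpoint tables with known injected AI-vs-clinical shifts.

    Clinical endpoint values are drawn around plausible head-and-neck
    magnitudes; each AI plan's endpoints equal the clinical value plus
    case-level noise plus, for the PTV-priority profile, the requested
    constant ``shifts`` (endpoint -> additive shift).  Used to verify that
    the commissioning report flags exactly the shifted endpoints.
    """
    rng = np.random.default_rng(seed)
    baseline = {
        "ci": 1.2, "hi": 9.5, "body_d1cc_gy": 47.5,
        "brainstem_d0p1cc_gy": 15.0, "cord_plus_5mm_d0p1cc_gy": 30.0,
        "parotid_l_dmedian_gy": 13.5, "parotid_r_dmedian_gy": 13.0,
        "oral_cavity_dmedian_gy": 19.0, "larynx_dmedian_gy": 18.0,
        "pharynx_dmedian_gy": 34.0, "mandible_d1cc_gy": 44.0,
        "total_mu": 1800.0,
    }
    shifts = dict(shifts or {})
    prof_p, prof_o = GROUP_PROFILES[group]
    group_sep = {"bilateral": 0.0, "left": -6.0, "right": 6.0}[group]

    cases = []
    for i in range(n_cases):
        clin = {}
        for ep in endpoints:
            base = baseline.get(ep, 10.0)
            clin[ep] = base + rng.normal(0.0, max(noise_sd, 0.05 * abs(base)))
        clin["parotid_l_dmedian_gy"] += group_sep / 2.0
        clin["parotid_r_dmedian_gy"] -= group_sep / 2.0
        clinical = pd.Series(clin)

        def perturb(extra: Mapping[str, float]) -> pd.Series:
            out = {}
            for ep in endpoints:
                out[ep] = clinical[ep] + rng.normal(0.0, noise_sd) + extra.get(ep, 0.0)
            return pd.Series(out)

        ai = {prof_p: perturb(shifts), prof_o: perturb({})}
        cases.append(CommissionCase(case_id=f"case{i:03d}", clinical=clinical, ai=ai))
    return cases
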