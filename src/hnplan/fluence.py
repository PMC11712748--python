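"""Fluence-map prediction: data contract, tradeoff profiles and baseline.

The six tradeoff profiles (BP/BO/LP/LO/RP/RO) combine a parotid-sparing
preference (both / left-only / right-only) with a PTV-vs-OAR priority.
Prediction is pluggable through a registry so alternative models can slot
in behind the same contract (nonnegative 128 x 128 grids, deterministic,
jaw-clip compliant); the shipped predictor is a deterministic conformal
baseline:

* a uniform aperture over the PTV interface channel above a threshold;
* a multiplicative attenuation w in [0, 1] over each spared parotid's BEV
  shadow — smaller w (more sparing) for OAR-priority profiles, and an
  extra focus factor when a single parotid is prioritised;
* Gaussian edge feathering and clipping to the beam's jaw rectangle.

The baseline's parameters are package defaults chosen for plausible
desk-scale behaviour, not clinically derived values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .geometry import FLUENCE_PIXEL_MM, FLUENCE_SHAPE, BeamTemplate, fluence_pixel_coords
from .projection import ProjectionStack

__all__ = [
    "FluenceMap",
    "TradeoffProfile",
    "PROFILES",
    "BaselineParams",
    "baseline_conformal",
    "predict_fluence",
    "register_predictor",
    "clip_to_jaws",
]


@dataclass
class FluenceMap:
    """One beam's nonnegative fluence grid in the isocenter plane."""

    values: np.ndarray
    beam_index: int
    pixel_mm: float = FLUENCE_PIXEL_MM
    jaw_clipped: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != FLUENCE_SHAPE:
            raise ValueError(f"fluence grid is {values.shape}, expected {FLUENCE_SHAPE}")
        if not np.all(np.isfinite(values)):
            raise ValueError("fluence contains non-finite values")
        if (values < 0).any():
            raise ValueError("fluence must be nonnegative")
        self.values = values


@dataclass(frozen=True)
class TradeoffProfile:
    label: str
    parotid_weighting: str   # both | left | right
    ptv_oar_preference: str  # PTV | OAR

    @property
    def spared_parotids(self) -> tuple[str, ...]:
        return {
            "both": ("l", "r"),
            "left": ("l",),
            "right": ("r",),
        }[self.parotid_weighting]


#: The six tradeoff scenarios: parotid weighting x PTV/OAR priority.
PROFILES: dict[str, TradeoffProfile] = {
    "BP": TradeoffProfile("BP", "both", "PTV"),
    "BO": TradeoffProfile("BO", "both", "OAR"),
    "LP": TradeoffProfile("LP", "left", "PTV"),
    "LO": TradeoffProfile("LO", "left", "OAR"),
    "RP": TradeoffProfile("RP", "right", "PTV"),
    "RO": TradeoffProfile("RO", "right", "OAR"),
}


@dataclass(frozen=True)
class BaselineParams:
    threshold: float = 0.05       # aperture cut on the normalised PTV channel
    parotid_threshold: float = 0.05
    feather_sigma_px: float = 1.0
    w_ptv_priority: float = 0.7   # parotid-shadow attenuation, PTV-first profiles
    w_oar_priority: float = 0.4   # stronger attenuation when OARs have priority
    w_focus: float = 0.6          # extra factor on the single prioritised parotid


def clip_to_jaws(values: np.ndarray, jaws_mm: Sequence[float],
                 pixel_mm: float = FLUENCE_PIXEL_MM) -> np.ndarray:
    """Zero fluence outside the jaw rectangle (pixel centres decide)."""
    x1, x2, y1, y2 = jaws_mm
    ug, vg = fluence_pixel_coords(values.shape, pixel_mm)
    inside = (
        (ug[:, None] >= x1) & (ug[:, None] <= x2)
        & (vg[None, :] >= y1) & (vg[None, :] <= y2)
    )
    return np.where(inside, values, 0.0)


def baseline_conformal(stacks: Sequence[ProjectionStack], profile: TradeoffProfile,
                       template: BeamTemplate | None = None,
                       params: BaselineParams = BaselineParams()) -> list[FluenceMap]:
    """Deterministic conformal fluence from the anatomical stacks."""
    w = params.w_ptv_priority if profile.ptv_oar_preference == "PTV" else params.w_oar_priority
    maps = []
    for stack in stacks:
        ptv_ch = stack.channels["interface:ptv"]
        f = (ptv_ch > params.threshold).astype(np.float64)
        for side in profile.spared_parotids:
            shadow = stack.channels[f"interface:parotid_{side}"] > params.parotid_threshold
            w_side = w if profile.parotid_weighting == "both" else w * params.w_focus
            f[shadow] *= w_side
        if params.feather_sigma_px > 0:
            f = ndimage.gaussian_filter(f, sigma=params.feather_sigma_px)
        clipped = False
        if template is not None and template.jaws_mm:
            f = clip_to_jaws(f, template.jaws_mm[stack.beam_index], stack.pixel_mm)
            clipped = True
        maps.append(FluenceMap(np.maximum(f, 0.0), stack.beam_index,
                               stack.pixel_mm, jaw_clipped=clipped))
    return maps


Predictor = Callable[..., list[FluenceMap]]

_REGISTRY: dict[str, Predictor] = {"baseline": baseline_conformal}


def register_predictor(name: str, fn: Predictor) -> None:
    _REGISTRY[name] = fn


def predict_fluence(stacks: Sequence[ProjectionStack], profile: str | TradeoffProfile,
                    predictor: str = "baseline",
                    template: BeamTemplate | None = None,
                    **kwargs) -> list[FluenceMap]:
    """Run a registered predictor over one template's projection stacks."""
    if isinstance(profile, str):
        try:
            profile = PROFILES[profile]
        except KeyError:
            raise ValueError(
                f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}"
            ) from None
    try:
        fn = _REGISTRY[predictor]
    except KeyError:
        raise ValueError(
            f"unknown predictor {predictor!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return fn(stacks, profile, template=template, **kwargs)
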