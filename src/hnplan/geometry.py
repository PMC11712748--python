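"""Template-plan automation: isocenter, gantry layout and jaw fitting.

Beam frame convention (IEC gantry scale, head-first supine patient system
with x = patient-left, y = posterior, z = superior):

* gantry 0: source anterior, beam travels +y;
* gantry 90: source on the patient's left, beam travels -x;
* the beam axis direction is ``d = (-sin g, cos g, 0)``, the beam's-eye-view
  in-plane axes are ``u = (cos g, sin g, 0)`` (crossplane) and
  ``v = (0, 0, 1)`` (inplane, +v superior).

"Counterclockwise from 180°" is interpreted as decreasing IEC gantry angle
(180 -> 140 -> ... ), which yields the conventional evenly spaced 9-beam
head-and-neck layout; the direction is a parameter since either sense keeps
the beams evenly distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import Role, StructureSet

__all__ = [
    "BeamTemplate",
    "beam_unit_vectors",
    "source_position",
    "bev_project_points",
    "place_isocenter",
    "place_beams",
    "fit_jaws",
]

#: Fluence / projection grid: 128 x 128 pixels at 2.5 mm in the isocenter plane.
FLUENCE_SHAPE = (128, 128)
FLUENCE_PIXEL_MM = 2.5


@dataclass
class BeamTemplate:
    """Isocenter, ordered gantry angles and per-beam jaw rectangles.

    Jaws are (x1, x2, y1, y2) in mm in the isocenter plane: x along the BEV
    u axis, y along v (superior positive); x1 < x2, y1 < y2.
    """

    isocenter_mm: tuple[float, float, float]
    gantry_deg: list[float]
    jaws_mm: list[tuple[float, float, float, float]] = field(default_factory=list)
    sad_mm: float = 1000.0

    @property
    def n_beams(self) -> int:
        return len(self.gantry_deg)

    def validate(self) -> None:
        for j in self.jaws_mm:
            x1, x2, y1, y2 = j
            if not (x1 < x2 and y1 < y2):
                raise ValueError(f"degenerate jaw rectangle {j}")


def beam_unit_vectors(gantry_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BEV frame (u, v, d) for a gantry angle: crossplane, inplane, beam axis."""
    g = np.deg2rad(gantry_deg)
    d = np.array([-np.sin(g), np.cos(g), 0.0])
    u = np.array([np.cos(g), np.sin(g), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    return u, v, d


def source_position(isocenter_mm, gantry_deg: float, sad_mm: float) -> np.ndarray:
    _, _, d = beam_unit_vectors(gantry_deg)
    return np.asarray(isocenter_mm, float) - sad_mm * d


def bev_project_points(points_mm: np.ndarray, isocenter_mm, gantry_deg: float,
                       sad_mm: float) -> np.ndarray:
    """Divergent projection of 3D points onto the isocenter plane.

    Each point is projected along the line from the beam source through the
    point; returns (n, 2) BEV coordinates (u, v) in mm.
    """
    iso = np.asarray(isocenter_mm, float)
    u, v, d = beam_unit_vectors(gantry_deg)
    src = iso - sad_mm * d
    rel = np.atleast_2d(points_mm) - src
    denom = rel @ d
    if np.any(denom <= 0):
        raise ValueError("points behind or at the beam source cannot be projected")
    t = sad_mm / denom
    q = src + t[:, None] * rel - iso
    return np.stack([q @ u, q @ v], axis=1)


def fluence_pixel_coords(shape=FLUENCE_SHAPE, pixel_mm: float = FLUENCE_PIXEL_MM):
    """BEV (u, v) coordinates of fluence pixel centres, centred on the axis."""
    nu, nv = shape
    ug = (np.arange(nu) - (nu - 1) / 2.0) * pixel_mm
    vg = (np.arange(nv) - (nv - 1) / 2.0) * pixel_mm
    return ug, vg


def _round_to(value: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(value, float) / step) * step


def place_isocenter(structures: StructureSet, *, fallback_distance_mm: float = 25.0,
                    rounding_mm: float = 5.0) -> np.ndarray:
    """Place the isocenter at the centre of the highest-prescription PTV.

    Falls back to the primary PTV's centroid when the highest-dose PTV's
    centroid lies farther than ``fallback_distance_mm`` from it (large
    isocenter shifts move the beam divergence away from template
    conditions).  Each coordinate, expressed relative to the CT origin, is
    rounded to the nearest ``rounding_mm`` for patient-setup convenience.

    The primary PTV is the lowest-prescription PTV (ties broken by larger
    volume); a tie in the highest prescription across disjoint PTVs is an
    error requiring user disambiguation.
    """
    ptvs = [n for n in structures.names_with_role(Role.PTV) if n in structures.rx_gy]
    if not ptvs:
        raise ValueError("no PTV-role structure with a prescription")
    rx = {n: structures.rx_gy[n] for n in ptvs}
    top_rx = max(rx.values())
    top = [n for n, r in rx.items() if r == top_rx]
    if len(top) > 1:
        raise ValueError(
            f"PTVs {top} share the highest prescription {top_rx} Gy; "
            "ambiguous isocenter target"
        )
    low_rx = min(rx.values())
    primaries = sorted(
        (n for n, r in rx.items() if r == low_rx),
        key=structures.volume_cc, reverse=True,
    )
    primary = primaries[0]

    target = structures.centroid_mm(top[0])
    primary_c = structures.centroid_mm(primary)
    if np.linalg.norm(target - primary_c) > fallback_distance_mm:
        target = primary_c

    origin = np.asarray(structures.reference.origin_mm)
    return origin + _round_to(target - origin, rounding_mm)


def place_beams(isocenter_mm=None, n_beams: int = 9, start_deg: float = 180.0,
                step_deg: float = 40.0, direction: str = "ccw") -> list[float]:
    """Evenly distributed gantry angles starting at ``start_deg``.

    ``direction='ccw'`` decreases the IEC angle each step (180, 140, ...);
    the isocenter argument is accepted for interface symmetry but the
    angles do not depend on it.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if n_beams * step_deg > 360.0 + 1e-9:
        raise ValueError("beam fan exceeds 360 degrees")
    sign = -1.0 if direction == "ccw" else 1.0
    return [float((start_deg + sign * step_deg * k) % 360.0) for k in range(n_beams)]


def fit_jaws(structures: StructureSet, template: BeamTemplate,
             margin_mm: float = 7.0, *, shoulder_clearance_mm: float = 5.0,
             min_ptv_coverage: float = 0.98,
             max_field_mm: float = 400.0) -> list[tuple[float, float, float, float]]:
    """Per-beam collimator jaws from the PTV's divergent BEV footprint.

    Jaws are the bounding box of the PTV's beam's-eye-view projection
    expanded by ``margin_mm``.  For beams whose field would include the
    shoulder landmark, the inferior jaw edge is raised to just above the
    shoulder's BEV top (plus clearance) — mimicking the planner's balance
    of shoulder beam entrance against PTV coverage — but never so far that
    the retained PTV BEV fraction drops below ``min_ptv_coverage``.
    """
    ptv_names = structures.names_with_role(Role.PTV)
    if not ptv_names:
        raise ValueError("no PTV structure for jaw fitting")
    # Union of all PTVs defines the field requirement.
    ptv_mask = np.zeros(structures.reference.shape, dtype=bool)
    for n in ptv_names:
        ptv_mask |= structures[n]
    ptv_pts = structures.reference.index_to_world(np.argwhere(ptv_mask))

    shoulder_pts = None
    if "shoulders" in structures and structures["shoulders"].any():
        shoulder_pts = structures.reference.index_to_world(
            np.argwhere(structures["shoulders"])
        )

    jaws = []
    for gantry in template.gantry_deg:
        uv = bev_project_points(ptv_pts, template.isocenter_mm, gantry, template.sad_mm)
        x1, y1 = uv.min(axis=0) - margin_mm
        x2, y2 = uv.max(axis=0) + margin_mm
        if (x2 - x1) > max_field_mm or (y2 - y1) > max_field_mm:
            raise ValueError(
                f"PTV BEV projection at gantry {gantry} needs a "
                f"{x2 - x1:.0f} x {y2 - y1:.0f} mm field, exceeding "
                f"{max_field_mm:.0f} mm"
            )
        if shoulder_pts is not None:
            suv = bev_project_points(
                shoulder_pts, template.isocenter_mm, gantry, template.sad_mm
            )
            in_field = (
                (suv[:, 0] >= x1) & (suv[:, 0] <= x2)
                & (suv[:, 1] >= y1) & (suv[:, 1] <= y2)
            )
            if in_field.any():
                raised = float(suv[in_field, 1].max()) + shoulder_clearance_mm
                # coverage guard: keep at least min_ptv_coverage of PTV BEV points
                cap = float(np.quantile(uv[:, 1], 1.0 - min_ptv_coverage))
                y1 = max(y1, min(raised, cap))
        jaws.append((float(x1), float(x2), float(y1), float(y2)))
    return jaws
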