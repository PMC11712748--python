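"""Three-step pause-review-continue planning workflow over a case directory.

Step 1 validates the structure mapping and writes the automated template
(isocenter, 9 gantry angles, per-beam jaws), honouring planner overrides.
Step 2 builds the per-beam anatomical stacks and predicts fluence for the
requested tradeoff profiles.  Step 3 runs the dose engine, normalises to
the prescription, evaluates the endpoint row and (optionally) gamma-checks
against a supplied reference dose.

A JSON run manifest records the structure mapping, config, seeds and step
completion so a rerun is fully determined; in canonical mode timestamps
are suppressed so reruns are byte-reproducible.

An automatic fine-tuning hook is exposed but is a documented no-op: the
package ships no optimizer, only the interface where one would plug in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .dose import EngineParams, compute_dose, normalize_to_prescription
from .evaluate import dvh, endpoint_table
from .fluence import PROFILES, predict_fluence
from .geometry import BeamTemplate, fit_jaws, place_beams, place_isocenter
from .projection import beam_traversal, build_stack
from .qa import gamma_index
from .volumes import STANDARD_STRUCTURES, StructureSet, VoxelVolume

__all__ = ["RunManifest", "step1_prepare", "step2_predict", "step3_finalize", "run_all"]

log = logging.getLogger("hnplan.workflow")

#: Hook point for automatic plan fine-tuning; intentionally the identity.
FineTuneHook = Callable[[VoxelVolume, StructureSet], VoxelVolume]


def no_fine_tuning(dose: VoxelVolume, structures: StructureSet) -> VoxelVolume:
    return dose


@dataclass
class RunManifest:
    case_id: str
    mapping: dict[str, str] = field(default_factory=dict)  # user name -> standard name
    profiles: list[str] = field(default_factory=list)
    overrides: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    canonical: bool = False
    steps: dict[str, str] = field(default_factory=dict)

    def stamp(self, step: str) -> None:
        self.steps[step] = (
            "done" if self.canonical
            else datetime.now(timezone.utc).isoformat(timespec="seconds")
        )

    def require(self, step: str) -> None:
        if step not in self.steps:
            raise RuntimeError(f"step {step!r} has not been run yet")

    def save(self, case_dir) -> Path:
        path = Path(case_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, case_dir) -> "RunManifest":
        data = json.loads((Path(case_dir) / "manifest.json").read_text())
        return cls(**data)


def _load_case(case_dir) -> tuple[VoxelVolume, StructureSet]:
    case_dir = Path(case_dir)
    ct = hio.read_volume(case_dir / "ct.nrrd")
    structures = hio.read_structures(case_dir / "structures", ct)
    return ct, structures


def _apply_mapping(structures: StructureSet, mapping: dict[str, str]) -> StructureSet:
    if not mapping:
        return structures
    renamed = StructureSet(structures.reference)
    for name in structures.names:
        target = mapping.get(name, name)
        renamed.add(target, structures[name], structures.roles[name],
                    rx_gy=structures.rx_gy.get(name))
    return renamed


def step1_prepare(case_dir, mapping: dict[str, str] | None = None,
                  overrides: dict | None = None, *, n_beams: int = 9,
                  start_deg: float = 180.0, step_deg: float = 40.0,
                  jaw_margin_mm: float = 7.0, sad_mm: float = 1000.0,
                  canonical: bool = False, seed: int = 0) -> RunManifest:
    """Structure sanity checks + automated template; writes plan.json."""
    case_dir = Path(case_dir)
    ct, structures = _load_case(case_dir)
    structures = _apply_mapping(structures, mapping or {})

    missing = [n for n in STANDARD_STRUCTURES if n not in structures]
    if missing:
        raise ValueError(
            f"unmapped required structures {missing}; available: {structures.names}"
        )
    overrides = overrides or {}

    if "isocenter_mm" in overrides:
        iso = np.asarray(overrides["isocenter_mm"], float)
        log.info("isocenter override honoured: %s", iso.tolist())
    else:
        iso = place_isocenter(structures)
    gantry = place_beams(iso, n_beams=n_beams, start_deg=start_deg, step_deg=step_deg)
    template = BeamTemplate(tuple(iso), gantry, sad_mm=sad_mm)
    template.jaws_mm = fit_jaws(structures, template, margin_mm=jaw_margin_mm)
    for beam_str, jaw in overrides.get("jaws_mm", {}).items():
        template.jaws_mm[int(beam_str)] = tuple(jaw)
    template.validate()

    plan = {
        "isocenter_mm": list(map(float, iso)),
        "gantry_deg": gantry,
        "jaws_mm": [list(j) for j in template.jaws_mm],
        "sad_mm": sad_mm,
    }
    (case_dir / "plan.json").write_text(json.dumps(plan, indent=2))

    manifest = RunManifest(
        case_id=case_dir.name, mapping=mapping or {}, overrides=overrides,
        config={"n_beams": n_beams, "start_deg": start_deg, "step_deg": step_deg,
                "jaw_margin_mm": jaw_margin_mm, "sad_mm": sad_mm},
        seed=seed, canonical=canonical,
    )
    manifest.stamp("step1")
    manifest.save(case_dir)
    return manifest


def load_template(case_dir) -> BeamTemplate:
    plan = json.loads((Path(case_dir) / "plan.json").read_text())
    return BeamTemplate(tuple(plan["isocenter_mm"]), plan["gantry_deg"],
                        [tuple(j) for j in plan["jaws_mm"]], plan["sad_mm"])


def step2_predict(case_dir, profiles: Sequence[str] | None = None,
                  predictor: str = "baseline") -> RunManifest:
    """Build anatomical stacks and predict fluence per tradeoff profile."""
    case_dir = Path(case_dir)
    manifest = RunManifest.load(case_dir)
    manifest.require("step1")
    profiles = list(profiles) if profiles else sorted(PROFILES)
    unknown = [p for p in profiles if p not in PROFILES]
    if unknown:
        raise ValueError(f"unknown profiles {unknown}")

    ct, structures = _load_case(case_dir)
    structures = _apply_mapping(structures, manifest.mapping)
    template = load_template(case_dir)

    traversals = [beam_traversal(ct, template, b) for b in range(template.n_beams)]
    stacks = [build_stack(ct, structures, template, b, traversal=traversals[b])
              for b in range(template.n_beams)]
    for profile in profiles:
        fmaps = predict_fluence(stacks, profile, predictor=predictor, template=template)
        for fmap in fmaps:
            hio.write_fluence(fmap, case_dir / "fluence" / profile / f"beam{fmap.beam_index}.txt")
        log.info("profile %s: %d fluence maps written", profile, len(fmaps))

    manifest.profiles = profiles
    manifest.config["predictor"] = predictor
    manifest.stamp("step2")
    manifest.save(case_dir)
    return manifest


def step3_finalize(case_dir, profile: str, rx_gy: float = 44.0,
                   engine: EngineParams = EngineParams(),
                   reference_dose_path=None,
                   fine_tune: FineTuneHook = no_fine_tuning) -> RunManifest:
    """Dose, normalisation, endpoints and optional gamma for one profile."""
    case_dir = Path(case_dir)
    manifest = RunManifest.load(case_dir)
    manifest.require("step2")
    if profile not in manifest.profiles:
        raise ValueError(f"profile {profile!r} was not predicted in step 2")

    ct, structures = _load_case(case_dir)
    structures = _apply_mapping(structures, manifest.mapping)
    template = load_template(case_dir)
    fdir = case_dir / "fluence" / profile
    fluences = [hio.read_fluence(fdir / f"beam{b}.txt") for b in range(template.n_beams)]

    dose = compute_dose(ct, structures, template, fluences, engine)
    dose, scale = normalize_to_prescription(dose, structures["ptv"], rx_gy)
    dose = fine_tune(dose, structures)

    out_dir = case_dir / "eval" / profile
    out_dir.mkdir(parents=True, exist_ok=True)
    hio.write_volume(dose, out_dir / "dose.nrrd")
    endpoints = endpoint_table(dose, structures, rx_gy, fluences=fluences, label=profile)
    endpoints.to_csv(out_dir / "endpoints.csv", header=["value"])

    curves = {}
    for name in STANDARD_STRUCTURES:
        curves[name] = dvh(dose, structures[name], structure=name)
    top = max(float(c.dose_gy.max()) for c in curves.values())
    axis = np.arange(0.0, top + 0.1, 0.1)
    dvh_df = pd.DataFrame({"dose_gy": axis})
    for name, c in curves.items():
        dvh_df[name] = c.resample(axis).volume_pct
    dvh_df.to_csv(out_dir / "dvh.csv", index=False)

    if reference_dose_path is not None:
        ref = hio.read_volume(reference_dose_path, unit="Gy")
        mid = dose.shape[0] // 2
        res = gamma_index(ref.values[mid], dose.values[mid],
                          spacing_mm=(dose.spacing_mm[1], dose.spacing_mm[2]))
        (out_dir / "gamma.json").write_text(json.dumps({
            "gpr_pct": res.gpr_pct, "criteria": [res.dose_pct, res.dist_mm],
            "threshold_pct": res.threshold_pct, "mode": res.mode,
        }, indent=2))
    else:
        log.info("no reference dose supplied; gamma comparison skipped")

    manifest.config["normalization_scale"] = scale
    manifest.config["rx_gy"] = rx_gy
    manifest.stamp(f"step3:{profile}")
    manifest.save(case_dir)
    return manifest


def run_all(case_dir, profiles: Sequence[str] | None = None,
            rx_gy: float = 44.0, **step1_kwargs) -> RunManifest:
    """End-to-end pipeline on a prepared case directory."""
    step1_prepare(case_dir, **step1_kwargs)
    manifest = step2_predict(case_dir, profiles)
    for profile in manifest.profiles:
        manifest = step3_finalize(case_dir, profile, rx_gy=rx_gy)
    return manifest
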