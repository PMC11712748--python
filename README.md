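# hnplan

Desk-scale automation of head-and-neck (HN) IMRT treatment planning and of
the statistical commissioning workflow used to validate such automation —
exercisable entirely on synthetic phantoms, with no clinical data.

Clinical HN planning platforms automate three stages: (1) template-plan
preparation (isocenter placement, a 9-beam gantry layout, per-beam
collimator jaws fitted around the target while respecting shoulder beam
entrance), (2) per-beam fluence-map prediction from beam's-eye-view (BEV)
anatomical projections, and (3) dose calculation, prescription
normalisation and dose-volume evaluation.  Commissioning such a platform
means comparing automated plans against reference plans endpoint by
endpoint with paired statistics, and verifying deliverability with
gamma-index QA.  `hnplan` implements every one of those pieces at desk
scale so each rule and metric can be tested against analytic and
brute-force oracles:

- **phantom** — synthetic bilateral-neck phantoms: CT-like HU volume, the
  ten modeled structures (primary PTV, primary CTV, brainstem, cord+5 mm,
  left/right parotid, oral cavity, larynx, pharynx, mandible) and
  lung/shoulder landmarks, built from analytic solids with controllable
  PTV–parotid overlap and left/right asymmetry.
- **geometry** — isocenter at the centre of the highest-prescription PTV,
  falling back to the primary PTV centroid beyond 25 mm, rounded to the
  nearest 5 mm per coordinate; 9 gantry angles at 40° spacing starting
  from 180°; divergent-projection jaw fitting with a shoulder-clearance
  rule.
- **projection** — exact Siddon-style ray traversal producing the
  12-channel anatomical input (interface projections of all 10 structures,
  intra-structure projections of PTV and CTV) on the 128 × 128 / 2.5 mm
  fluence grid.
- **fluence** — a pluggable predictor registry with six tradeoff profiles
  (BP/BO/LP/LO/RP/RO: bilateral/left/right parotid sparing × PTV-vs-OAR
  priority) and a deterministic conformal baseline predictor.
- **dose** — a transparent exponential-attenuation pencil engine with
  inverse-square and Gaussian lateral scatter, plus D95-based prescription
  normalisation (Rx covering 95% of the PTV).
- **evaluate** — cumulative DVHs and the standard endpoint row:
  conformity index CI = V_PR / V_PTV, heterogeneity index
  HI = (D2% − D98%) / Rx, D_x% / D_cc / median doses, and a total-MU proxy.
- **qa** — a gamma index (dose-difference / distance-to-agreement) with
  sub-pixel search, passing rates and a two-tier (3%/2 mm, fallback
  2%/4 mm) per-field report.
- **commission** — parotid-tradeoff case grouping, paired two-sided
  Wilcoxon signed-rank tests (exact sign-flip distribution for n ≤ 12)
  with Bonferroni correction, DVH median/quartile bands, and a
  machine-readable commissioning report.

## Worked example

```python
from hnplan import (PhantomSpec, generate_phantom, place_isocenter, place_beams,
                    fit_jaws, BeamTemplate, build_stack, predict_fluence,
                    compute_dose, normalize_to_prescription, endpoint_table)

ct, structures = generate_phantom(PhantomSpec(seed=1))
iso = place_isocenter(structures)
template = BeamTemplate(tuple(iso), place_beams(iso))
template.jaws_mm = fit_jaws(structures, template)
print(template.gantry_deg)
# [180.0, 140.0, 100.0, 60.0, 20.0, 340.0, 300.0, 260.0, 220.0]

stacks = [build_stack(ct, structures, template, b) for b in range(9)]
for label in ("BP", "LP"):
    fluences = predict_fluence(stacks, label, template=template)
    dose = compute_dose(ct, structures, template, fluences)
    dose, _ = normalize_to_prescription(dose, structures["ptv"], rx_gy=44.0)
    row = endpoint_table(dose, structures, 44.0, fluences=fluences)
    print(label, round(row["ci"], 2), round(row["parotid_l_dmedian_gy"], 1))
# BP 1.18 24.0
# LP 1.33 17.7
```

The two printed numbers per profile are the conformity index (prescription
isodose volume over PTV volume; 1.0 is perfectly conformal) and the left
parotid's median dose in Gy.  The left-parotid profile (LP) lowers the
left-parotid median dose from 24.0 to 17.7 Gy at the cost of conformity —
the directional tradeoff the six profiles are designed to provide.  The
baseline conformal predictor is far blunter than a trained model or an
inverse optimiser, so absolute plan quality (HI in particular) is not
clinical-grade; the pipeline semantics, metrics and statistics are what
the package validates.

The same pipeline is available from the shell:

```bash
hnplan phantom --out case0 --seed 1
hnplan template case0
hnplan predict case0 --profile BP --profile LP
hnplan finalize case0 --profile BP
```

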