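# Methods

This note documents the models, conventions and numerical choices behind
`hnplan`, and what its synthetic validation does and does not demonstrate.

## Coordinate and grid conventions

All geometry lives in patient coordinates in millimetres with axes
(x: patient-left, y: posterior, z: superior), the common DICOM patient
system for a head-first supine patient.  Arrays are indexed
`values[ix, iy, iz]` so array axis k is patient axis k; `origin_mm` is the
centre of voxel (0, 0, 0).  A single convention shared by the phantom,
ray tracer, dose engine and I/O avoids silent axis flips between modules;
SimpleITK's (z, y, x) array order is transposed at the I/O boundary.

Beam frames use the IEC gantry scale: gantry 0 enters from anterior,
gantry 90 from the patient's left.  The beam's-eye-view (BEV) axes are
u = (cos g, sin g, 0) (crossplane) and v = +z (inplane, superior
positive).  "Starting from 180° counterclockwise" is realised as
*decreasing* IEC angle (180, 140, …, 220), which reproduces the
conventional evenly spaced 9-beam layout; the sense is a parameter
(`direction`) because either interpretation keeps the beams evenly
distributed and the rest of the pipeline is insensitive to it.

## Synthetic phantom

The phantom emulates a bilateral neck target prescribed 44 Gy (an optional
sequential-boost target at 70 Gy) inside an elliptic-cylinder body with a
wider shoulder slab, lung apices (HU ≈ −700), a vertebral bone annulus and
a bone mandible (HU ≈ 700), soft tissue at HU ≈ 40, and seeded Gaussian HU
noise per tissue class.  All ten modeled structures are analytic solids —
ellipsoids, vertical cylinders, a half cylindrical shell — so each voxel-
counted volume can be checked against a closed form (the suite requires
agreement within 10%; the observed worst case is ~7% at the default
2.5 mm grid).  Axial extents of cylindrical solids use half-open z
intervals so lattice-aligned bounds contribute exactly their nominal
height.

Controllable geometry: `overlap_fraction` sets the fraction of each
parotid inside the PTV (solved by bisection on the parotid's lateral
offset; zero overlap places a 3 mm gap), `asymmetry` scales the left
parotid, and `seed` fixes all randomness — identical spec + seed is
bit-identical.  The default overlap of 0.1 reflects the common clinical
situation where the parotids abut and partially overlap a bilateral neck
PTV; it also guarantees the parotid-sparing profiles have a real tradeoff
to exercise.

What the phantom does **not** emulate: realistic anatomy (organ shapes are
convex solids), heterogeneity inside organs, contouring variability, and
patient-to-patient anatomical variation beyond the exposed parameters.
Tests passing on phantoms therefore validate the *rules and metrics* of
the platform, not clinical plan quality.

## Template automation

The isocenter is the centroid (unweighted mean of voxel centres) of the
highest-prescription PTV; if that point is more than 25 mm (Euclidean)
from the primary PTV's centroid, the primary centroid is used instead —
large shifts would move beam divergence away from the conditions a
template-trained predictor expects.  The "primary PTV" is the
lowest-prescription PTV, ties broken by larger volume; a tie in the
*highest* prescription across disjoint PTVs raises an error because the
rule is ambiguous.  Each coordinate is then rounded to the nearest 5 mm
*relative to the CT origin* (rounding per axis rather than on the shift
magnitude; both the reference point and the per-axis choice are exposed
as parameters since conventions differ between institutions).

Jaws per beam are the bounding box of the divergent BEV projection of the
PTV (every mask voxel centre projected through the source onto the
isocenter plane) expanded by a 7 mm margin (default, configurable).  When
the shoulder landmark's BEV footprint intersects the field, the inferior
jaw edge is raised to the shoulder footprint's top plus a 5 mm clearance —
one concrete instantiation of the planner's balance between shoulder beam
entrance and target coverage — but never above the v-quantile that would
clip more than `1 - min_ptv_coverage` (default 2%) of the PTV's BEV
points.  The shoulder rule only ever moves the inferior edge.  Fields
wider than 400 mm are rejected.

## Projections

`trace_rays` is an exact incremental grid traversal (Siddon-style): all
grid-plane crossing parameters are computed per ray, sorted, and turned
into (segment length, voxel index) lists whose lengths sum to the
in-volume chord exactly — testable against analytic chords and reversible
under ray inversion.  The same traversal is shared by the projections and
the dose engine, so it is exercised from two directions.

CT values are mapped to relative electron density via a piecewise-linear
table ((−1000, 0), (0, 1), (1000, 1.55), (3000, 2.5)) and integrated along
each fluence-pixel ray:

- *intra-structure* channels integrate density only inside the mask;
- *interface* channels integrate density from the ray's first entry into
  the body surface to its last exit from the structure (zero if the ray
  misses the structure).

Summation (a true line integral, units of density·mm) is the default
aggregation; a mean-along-chord alternative is exposed because any
monotone per-channel scaling is an acceptable input to a predictor, and
each channel is max-normalised to [0, 1] anyway.  Channels live on the
128 × 128, 2.5 mm grid centred on the beam axis; SAD defaults to 1000 mm
(standard linac).

## Fluence prediction

The predictor interface is a registry: any callable taking the nine
stacks and a tradeoff profile and returning nine nonnegative fluence
grids can be slotted in (a trained network would be registered the same
way).  The shipped baseline is deliberately simple and fully
deterministic: a uniform aperture over the thresholded PTV interface
channel (threshold 0.05 of the normalised channel), a multiplicative
attenuation over each spared parotid's BEV shadow, Gaussian edge
feathering (σ = 1 pixel), and jaw clipping.  The attenuation encodes the
six profiles: w = 0.7 for PTV-priority and w = 0.4 for OAR-priority
profiles, with a further ×0.6 focus factor when a single parotid is
prioritised (so LP spares the left parotid more aggressively than BP
does).  These four constants are package defaults chosen to produce
clearly separated, directionally correct tradeoffs at desk scale — they
are not fitted to any clinical data.

## Dose engine

Each fluence pixel deposits along its divergent ray:

    dose ∝ fluence · exp(−μ · radiological_depth) · (SAD / r)² · segment_length

with μ = 0.005 mm⁻¹ (water-equivalent), radiological depth the cumulative
density line integral to the segment midpoint, and r the distance from
the source.  Beam deposits are summed, convolved with an isotropic 3D
Gaussian (σ = 4 mm) for lateral scatter, and zeroed outside the body
expanded by a 10 mm buildup margin.  The engine is linear in fluence,
additive over beams and bit-reproducible.  It is a transparent stand-in
chosen for testability (the central-axis depth profile matches its closed
form within 2%), with head-and-neck-plausible falloff; it is not a
convolution/superposition or Monte Carlo algorithm and no claim of
clinical dosimetric accuracy is made.

Prescription normalisation applies a single scalar so that D95%(PTV)
equals the prescription exactly; D_q% is computed by linear interpolation
on the sorted voxel doses (equivalent to interpolated inversion of the
cumulative DVH), which makes normalisation idempotent.  Plans at other
prescription levels are rescaled linearly (e.g. 50 → 44 Gy, factor 0.88).
The total-MU proxy is `calibration · Σ_beams max(fluence)` — a relative
delivery-effort measure, not clinical monitor units.

## Evaluation metrics

CI = V_PR / V_PTV with the prescription isodose volume counted over BODY
(the standard convention; a PTV-only variant is a flag).  HI =
(D2% − D98%) / Rx, reported ×100 to match the usual clinical scale, with
the raw fraction available.  D_cc converts absolute volume to a
percentage of the structure volume using the voxel size, then
interpolates on sorted doses; requesting more cc than the structure
volume is an error.  DVHs are voxel-counted cumulative histograms on a
uniform dose grid (default bin 0.1 Gy).  Median doses can equivalently be
computed from voxel lists or fine DVH bins; differences are sub-bin and
both routes are exposed.

## Gamma QA

For every evaluated point above the low-dose threshold, γ is the minimum
over a reference-search neighbourhood of
√((Δdose/dose_crit)² + (Δr/dist_crit)²), with the reference resampled by
bilinear interpolation on a displacement lattice of step dist_crit/10
within a radius of 3 × dist_crit.  Defaults follow portal-dosimetry
convention: global normalisation to the reference maximum and a 10%
low-dose threshold (applied to the evaluated grid); both are parameters,
as is local normalisation.  γ ≤ 1 is inclusive at float precision.  The
two-tier field report evaluates each field at 3%/2 mm and re-tests
failures (GPR < 95%) at 2%/4 mm, reporting mean ± SD GPR.

## Commissioning statistics

Cases are grouped by the reference plan's parotid tradeoff: bilateral
when |ΔD_median| between parotids is ≤ τ (default 3 Gy — the grouping
criterion is inherently qualitative, so τ is exposed and reported),
otherwise the lower-dose side's group.  Within each group three paired
comparisons per endpoint are run (reference vs PTV-priority plan,
reference vs OAR-priority plan, PTV- vs OAR-priority), two-sided Wilcoxon
signed-rank, zeros dropped, at least 5 informative pairs required.  For
n ≤ 12 the exact sign-flip distribution is enumerated via a subset-sum
recursion over doubled mid-ranks (tie-aware, equivalent to enumerating
all 2ⁿ sign assignments); larger n uses the normal approximation with tie
and continuity corrections.  Bonferroni correction uses the endpoint
family as the unit (m = number of endpoint rows, 12 for the standard set;
m is configurable since the family convention is a choice).  IQRs are
Q3 − Q1 with linear-interpolation quantiles.  DVH bands resample all
curves to a common dose axis and take the pointwise median and 25–75
percentiles of percentage volume.

The synthetic commissioning generator draws clinical endpoint values
around plausible head-and-neck magnitudes and creates paired AI endpoints
as clinical + noise + optional constant shifts, so the report's detection
behaviour can be verified against known ground truth (the suite checks
that exactly the shifted endpoints are flagged at n = 18 with shifts of
several noise SDs).

## Problem sizes and runtime choices

The default phantom is 96³ voxels at 2.5 mm (24 cm cube) — large enough
for the ten structures and the shoulder slab at the native fluence-grid
resolution.  Pipeline-level tests use the same anatomy on coarser grids
(48³ at 5 mm; 64³ at 3.75 mm for dosimetric tradeoff checks), chosen so
the whole suite and the acceptance script each complete in a couple of
minutes on one CPU.  Oracle tests (projection sums, gamma brute force,
Wilcoxon enumeration) run on deliberately tiny inputs (≤ 32³ grids, 5 × 5
planes, n ≤ 12 samples) where exhaustive reference computations are
feasible.

## Known limitations

- The baseline predictor produces far more heterogeneous target dose than
  an optimiser or trained model (HI on the ×100 scale of tens, not ~10);
  only directional tradeoff behaviour is asserted.
- The dose engine ignores buildup, beam hardening, MLC transmission and
  leaf sequencing.
- The phantom's convex solids make BEV projections smoother than real
  anatomy; interface channels of concave organs would be less separable.
- The DICOM-RT ingest is minimal: single-frame axial CT series with
  identity orientation and planar CLOSED_PLANAR contours.
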