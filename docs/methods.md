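# Methods

This note records the models, conventions and numerical choices behind
`ldrtplan`, and what the synthetic study conditions do and do not show about
real patients.

## Coordinate and voxel conventions

All volumes live on one axis-aligned grid: axis 0 = left-right, axis 1 =
anterior-posterior, axis 2 = inferior-superior with superior = increasing z;
physical positions are millimetres at voxel centers with 0-based indices.
Membership of a voxel in any region (lesion, body, expansion) is decided by
its center point — no partial-volume weighting anywhere. This single rule
makes voxelization, margin expansion and DVH computation mutually consistent
and lets brute-force oracles check each operation exactly.

## Synthetic phantom

The phantom emulates the inputs of an LDRT planning study: a body
(elliptical cylinder, density 1), an ellipsoidal liver reference region
with SUV ~ N(μ, σ²) (defaults μ = 1.0, σ = 0.2), Gaussian background uptake
inside the body (mean 0.8, sd 0.1, clipped at 0), and ellipsoidal lesions
with uniform SUV (defaults 3–8) overriding whatever they overlap. The
`liver_mask` is *normal* liver: voxels claimed by a lesion are excluded, as
a physician contouring "normal liver" would.

Day-of-treatment variants re-generate the phantom from a perturbed
specification with the same noise seed, so an identity change is
voxel-identical, a removed lesion's voxels revert to background exactly, and
pure shifts are invertible on the ground-truth records. Magnitudes are user
parameters; the bundled `super_margin_change` moves every lesion 12–18 mm in
SI or scales it by 1.5–1.7 — deliberately beyond the 1 cm PTV margin, the
regime in which an un-adapted plan must fail.

Not modelled: PET physics (scatter, point-spread, decay correction),
CT Hounsfield calibration, organ deformation beyond rigid lesion motion and
global body scaling. Passing tests therefore demonstrate the *logic* of the
workflow under controlled geometry, not performance on clinical images.

## Segmentation

Threshold = liver sample mean + 2 × sample (n−1) standard deviation,
computed under the liver mask. Comparison is inclusive (SUV ≥ threshold):
the value is a *lower* bound for disease. Components are separated with
6-connectivity (face adjacency), the conservative choice that never merges
across a diagonal. Components below `min_volume_cc` (default 0.1 cc) are
discarded — the automated stand-in for manual review. With independent
per-voxel noise at coarse (4 mm) spacing, two-voxel noise islands can
survive the 0.1 cc default; a practitioner working at that resolution should
raise the filter (the CLI example uses 0.3 cc). Real PET noise is spatially
correlated and this trade-off will differ.

One degenerate case is worth knowing: on a *noise-free* phantom the liver
sample σ is 0, so the image-derived threshold equals μ and the entire liver
clears it. Exact-recovery tests therefore construct the threshold from the
liver's nominal (μ, σ) rather than from the noiseless image.

## Margin expansion and planning structures

Expansion is metric, not structuring-element-iteration: a voxel joins the
expanded set iff its center is within the margin of some source voxel
center, so a 1 cm margin is 1 cm at any spacing. Anisotropic margins use a
per-direction half-ellipsoid acceptance test (each of the six anatomical
directions has its own reach; a zero margin admits no displacement on that
side). Isotropic expansion is computed by thresholding a Euclidean distance
transform; directional expansion by FFT convolution with the acceptance
element. PTVs are not cropped to the body by default — targets near the
skin would otherwise silently lose margin; a crop is available explicitly.

Derived structures carry a derivation record and are recomputed from their
sources after any anatomy change ("derivation replay"), which is what keeps
junction helpers consistent during adaptation.

## Plan geometry

Conventional sectioning: superior/inferior borders A/B are the PTV extremes
± 10 mm; C = A − B; N = ⌈C / 220 mm⌉ isocenters (220 mm is the conservative
working length under the 280 mm field limit; the ceiling is the only
rounding that never exceeds it); equal sections of length D = C/N with the
isocenter at each section's SI midpoint and lateral/AP position at the
centroid of the combined PTV voxel set, so inter-isocenter shifts are
couch-in/out only. A coverage check asserts every PTV voxel is within
140 mm SI of its section's isocenter.

Intent partitioning: the A..B span is divided into ⌈C / 385 mm⌉ equal
sections; any boundary cutting a target is moved into a target-free gap —
of the two gaps adjacent to the cut target block the larger wins, ties
going superior, landing at the gap midpoint. Targets are then assigned by
SI position; each group takes the minimal isocenter count for its span
(≤ 260 mm → 1, ≤ 385 mm → 2), a region label from a user-supplied SI→region
map, and that region's influencer organs (thorax: esophagus, heart, lungs,
trachea; abdomen: duodenum, liver, pancreas, stomach; pelvis: bladder,
rectum). A group still longer than 385 mm is re-partitioned recursively;
a single target over 385 mm is an error. When no target-free gap exists the
boundary stays put, targets are assigned whole by centroid, and the
resulting close pair surfaces through junction detection (< 5 mm SI gap
between targets of different intents; overlapping projections count as
gap ≤ 0).

Junction helpers for a superior/inferior pair (a, b): `PTV_a_Opti` =
PTV_a minus PTV_b expanded 30 mm laterally/AP and 5 mm toward head and
feet; `Junction_avoid` = the 3 mm band immediately inferior to PTV_a's
30 mm lateral/AP expansion (the band construction has two readings in the
source material; the implemented one — a thin inferior band abutting
PTV_a — is pinned by tests). Goals: the standard coverage goals transferred
to `PTV_a_Opti` with its hotspot bound tightened to 1.0 × Rx (P2); PTV_b as
avoidance with D_0.03cc < 0.5 Gy and V₁Gy < 2 % (both P4, strict); and
`Junction_avoid` V₂Gy ≤ 10 % (P2).

## Dose surrogate

`synthesize_dose` is explicitly **not** a dose engine. It produces
dose(x) = Rx · g(d(x)) · (1 + ripple), with d the Euclidean distance to the
nearest target voxel (0 inside), g = 1 inside and exp(−d²/2σ²) outside,
optional independent Gaussian ripple, a hard cap at `hotspot_factor` × Rx,
and per-structure avoidance caps. Defaults: σ = 6.8 mm — the half-dose
surface then sits σ√(2 ln 2) ≈ 8 mm outside the target, which yields R50 %
values in the mid single digits for centimetre-scale targets, the range a
well-optimized conformal plan occupies — ripple 0 (the noise-free conformal
ideal, under which prescription-isodose metrics are exact: CI = 1 for an
isolated target), hotspot cap 1.25.

Normalization scales the whole distribution by the unique factor making the
combined-PTV D_min,0.03cc equal 95 % of prescription; a DVH quantile is
linear in dose, so the factor is exact (machine precision) and idempotent.
It is off by default in `build_initial_plan` — clinically the rule is
applied selectively — but when a plan used it, the adapted plan re-applies
it, including the side effect that scaling up also scales hotspots (warned
when the factor exceeds 1.1). Note that normalizing a noise-free uniform
target dose necessarily pulls the whole target to 0.95 × Rx; this is a
property of near-minimum normalization itself, visible here because the
surrogate is perfectly homogeneous.

The "scheduled" plan is the initial dose frozen in room coordinates: under
the surrogate's homogeneous-medium approximation, recalculating on new
anatomy changes nothing — structures move, dose does not. The "adapted"
plan re-synthesizes dose around the day-of PTVs.

## Evaluation

DVHs are exact voxel lists (each voxel contributes its full volume at its
dose). Volume queries return the step value at the requested cumulative
volume; a query landing exactly on a plateau boundary resolves to the
conservative side — colder for near-minimum, hotter for near-maximum.
Goal grading is pass / variation / fail with a 10⁻⁹ relative slack on
non-strict comparisons (so an exactly-normalized value passes despite float
rounding); strict goals ("< 0.5 Gy") compare exactly. R50 % and CI measure
isodose volumes over the whole grid (a raw volume ratio); the D2cm search
region is restricted to the body contour, where surrogate dose is
meaningful. Cohort summaries report mean ± sample sd of per-plan goal
percentages, with absent goal classes as not-applicable rather than 0.

## Adaptive session

Day-of GTVs come from the day phantom's ground-truth lesion records —
standing in for physician-reviewed recontours — then PTVs and helpers are
re-derived by rule. Both plans are evaluated against the day-of goal set
(a vanished target simply has no goals). The availability gate withholds a
scheduled plan whose any-target mean dose is strictly below 0.5 × Rx.
Selection is lexicographic: more P1 goals passed, then more P2, then lower
D2cm, with an exact tie keeping the scheduled plan (no-adaptation default)
and an unavailable scheduled plan never winning. The rule is a
formalization: the clinical account reports evaluations and the outcome
(adapted always chosen), not an explicit decision procedure.

Timing: per-step ordinary least squares of duration on target count
(`scipy.stats.linregress`), r² = 0 by convention for constant durations;
the total model is the sum of step models with its own r² against summed
durations; an optional flag drops per-step observations more than 3 sd from
the step mean (off by default). Predictions clamp at zero with a warning.
The synthetic log generator plants near-flat influencer steps and
target-count-driven editing/planning steps, mirroring the qualitative
pattern of measured adaptive workflows; its absolute numbers are arbitrary.

## Problem sizes and determinism

Tests and the acceptance script use 48³–64×64×96 grids at 4 mm spacing for
phantoms, ≤ 33³ grids for oracle comparisons, 100 randomized sectioning
sets, 200 random dose/mask pairs and 50 adaptive sessions — sizes chosen so
the full suite runs in well under a minute while every check remains exact
or statistically powered (slope recovery is asserted within 3 standard
errors). All stochastic paths take explicit seeds; fixed seed ⇒ bit-identical
volumes.

## Known limitations

* The dose surrogate has no beam model, heterogeneity, or optimizer
  trade-offs; junction *dosimetry* (as opposed to junction geometry and
  goals) is only as realistic as the Gaussian-falloff model.
* Region assignment is an SI-range lookup, not anatomical segmentation.
* Influencer structures are metadata (they parameterize timing and intent
  templates); no organ contours are generated or deformed.
* The adaptive session does not model image registration or contour-editing
  error: day-of targets are exact ground truth, so adapted-plan quality is
  an upper bound.
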