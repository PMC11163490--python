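# ldrtplan

Planning-geometry and adaptive-session simulation for **conformal low-dose
radiotherapy (LDRT) of polymetastatic disease** — patients with dozens of
metastatic lesions spread across the whole trunk, treated with an immune-
stimulating 1 Gy prescription to *every* radiographically evident site.

Treating 5–52 targets at once pushes planning systems outside their usual
regime: the treated length far exceeds a single field, so the body must be
sectioned across multiple isocenters or split into independently optimized
planning units ("RT intents") with at most two co-optimized isocenters each;
abutting units create junction dose-gradient problems; and because lesions
move, regress and progress between fractions, the plan must be adapted
on-couch to the anatomy of the day.

`ldrtplan` implements that workflow end to end as a testable library:

* **phantom** — synthetic polymetastatic patients (PET-like SUV + CT-like
  density volumes) with known ground truth, plus day-of-treatment variants
  (movement, regression/disappearance, progression, body-habitus change);
* **segmentation** — GTV delineation by thresholding PET at the normal-liver
  SUV mean + 2σ, with connected-component target separation;
* **structures** — metric margin expansion (GTV + 1 cm → PTV), mask algebra
  and distance maps, and the standard planning helpers (`All_PTVs`,
  `NormalTissue`, `NormalTissue_2cm`);
* **plangeom** — conventional sectioning (N = ⌈C / 22 cm⌉ isocenters over the
  treated length C), RT-intent partitioning with the 26 cm / 38.5 cm
  single/dual-isocenter limits, junction detection (< 5 mm SI gap across
  intents), junction helper structures, field templates and clinical-goal
  sets (V₁Gy ≥ 95 %, D_min,0.03cc ≥ 0.95 Gy, D_0.03cc ≤ 1.20 Gy with
  acceptable variations);
* **dose** — a parametric conformal dose *surrogate* (prescription inside
  the target, Gaussian falloff outside) standing in for a commercial inverse
  optimizer, plus composite dose and the near-minimum normalization rule
  (D_min,0.03cc of all PTVs = 95 % of prescription);
* **evaluation** — exact voxel DVHs, tiered goal grading
  (pass / variation / fail, priorities P1–P4), and the plan-quality metrics
  R50 % = V₅₀%/V_PTV, CI = V₁₀₀%/V_PTV and D2cm (max dose ≥ 2 cm from any
  PTV, % of prescription);
* **adaptive** — the scheduled-vs-adapted session: the frozen initial dose
  re-evaluated on day-of structures vs. a re-conformed dose, an availability
  gate (any target mean dose < 50 % Rx withholds the scheduled plan),
  lexicographic plan selection, and a per-step linear timing model
  (duration vs. number of targets) for predicting adaptive time slots.

## Worked example

Partition a 31-target three-region case and count delivery geometry
(`examples/03_sectioning_and_intents.py`):

```text
treated length C = 1000 mm -> N = 5 isocenters, section length D = 200 mm
coverage violations: none

 region  targets  isocenters modality  fields_per_isocenter  fields  span_mm
 pelvis       10           1     IMRT                    12      12    220.0
abdomen       10           1     IMRT                    12      12    200.0
 thorax       11           2     IMRT                     9      18    310.0
totals: 42 IMRT fields, 4 isocenters, 31 targets
```

The thorax group spans more than 26 cm, so it needs two co-optimized
isocenters (9 fields each); with 12-field plans for abdomen and pelvis the
case totals 42 fixed fields over 4 isocenters.

Simulate an adaptive session in which one lesion moves 15 mm, one grows by
60 % and one disappears (`examples/06_adaptive_session.py`):

```text
reference: P1 goals passed 12/12, R50%=2.82, D2cm=1.3%
scheduled: P1 goals passed 6/10, R50%=3.19, D2cm=100.0%
adapted  : P1 goals passed 10/10, R50%=2.70, D2cm=1.3%
selected: adapted -- adapted passes more P1 goals (10 vs 6)
```

The frozen scheduled dose misses the moved and grown targets (and now
delivers full prescription ≥ 2 cm from any current PTV, D2cm = 100 %);
the adapted plan re-covers every remaining target and drops the vanished
target's goals.

The other examples cover phantom generation, segmentation, junction helper
derivation, dose evaluation and the timing model; each prints what it
computes and what the numbers mean.

A thin CLI wraps the same functions for shell use:

```bash
ldrtplan phantom-generate --config spec.yaml --out phantom/
ldrtplan segment --pet phantom/pet.nii.gz --liver phantom/liver.nii.gz \
    --body phantom/body.nii.gz --out gtvs/
ldrtplan plan-geometry --ptv-dir gtvs/ --mode conventional --out plan.json
ldrtplan timing-fit --records timing.csv --out model.json
```

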