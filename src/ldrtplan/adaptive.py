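"""Online-adaptive session simulation and workflow-duration modelling.

A session compares, on the anatomy of the day, the **scheduled** plan (the
initial dose frozen in room coordinates) against the **adapted** plan
(re-synthesized dose conforming to the day-of structures, which are
re-derived from the stored derivation rules: GTV recontour → 1 cm PTV
re-expansion → helper re-derivation).  Both are evaluated against the
day-of goal set; an availability gate mirrors the vendor's hard-coded
quality check (a scheduled plan with any target mean dose below 50 % of the
prescription is withheld), and plan selection is a lexicographic rule on
passed P1 goals, then P2 goals, then lower D2cm.

Workflow timing is modelled per step as an ordinary least-squares line in
the number of targets, giving a per-patient prediction of the adaptive
time slot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import Grid, StructureMask
from .dose import DoseGrid, DoseModelParams, normalize_dose, recalc_on_anatomy, synthesize_dose
from .evaluation import PlanEvaluation, evaluate_plan
from .phantom import AnatomyChangeSpec, Phantom, voxelize_lesion
from .plangeom import ClinicalGoal, RTIntent, build_goal_set, partition_intents
from .segmentation import compute_suv_threshold, segment_gtvs
from .structures import derive_planning_structures, expand_gtv_to_ptv, union_all

__all__ = [
    "PlanBundle",
    "AdaptiveSession",
    "TimingRecord",
    "StepFit",
    "TimingModel",
    "build_initial_plan",
    "run_session",
    "scheduled_availability",
    "select_plan",
    "fit_timing_model",
    "predict_session_duration",
    "generate_timing_records",
    "WORKFLOW_STEPS",
]

WORKFLOW_STEPS = (
    "generate_influencers",
    "edit_influencers",
    "generate_targets",
    "edit_targets",
    "generate_plans",
)

DEFAULT_REGION_MAP = [(-1e9, 1e9, "abdomen")]


@dataclass
class PlanBundle:
    """Everything the initial plan produced, kept for adaptation."""

    phantom: Phantom
    ptvs: list[StructureMask]
    all_ptvs: StructureMask
    external: StructureMask
    intents: list[RTIntent]
    goals: list[ClinicalGoal]
    dose: DoseGrid
    prescription: float = 1.0
    ptv_margin_mm: float = 10.0
    normalized: bool = True
    dose_params: DoseModelParams = field(default_factory=DoseModelParams)


def _truth_structures(phantom: Phantom, margin_mm: float) -> tuple[list[StructureMask], list[StructureMask]]:
    """GTV/PTV pairs voxelized from a phantom's ground-truth lesion records
    (the stand-in for physician-reviewed recontours)."""
    gtvs, ptvs = [], []
    for lesion in phantom.truth_lesions:
        m = voxelize_lesion(lesion, phantom.grid)
        if not m.any():
            continue
        gtv = StructureMask(f"GTV_{lesion.id}", m, phantom.grid, role="GTV")
        gtvs.append(gtv)
        ptvs.append(expand_gtv_to_ptv(gtv, margin_mm))
    return gtvs, ptvs


def build_initial_plan(
    phantom: Phantom,
    region_map: list[tuple[float, float, str]] | None = None,
    prescription: float = 1.0,
    ptv_margin_mm: float = 10.0,
    dose_params: DoseModelParams = DoseModelParams(),
    normalize: bool = False,
    segment_from_pet: bool = False,
    min_volume_cc: float = 0.1,
) -> PlanBundle:
    """Initial planning on a phantom: target definition, PTV expansion,
    intent partitioning, dose synthesis and (optionally) normalization.

    With ``segment_from_pet`` the GTVs come from liver-referenced SUV
    thresholding of the PET volume; otherwise from the ground-truth lesion
    records (equivalent on noise-free phantoms).
    """
    if segment_from_pet:
        thr = compute_suv_threshold(phantom.pet, phantom.liver_mask)
        gtvset = segment_gtvs(phantom.pet, thr, phantom.external_mask, min_volume_cc)
        gtvs = list(gtvset.gtvs)
        ptvs = [expand_gtv_to_ptv(g, ptv_margin_mm) for g in gtvs]
    else:
        gtvs, ptvs = _truth_structures(phantom, ptv_margin_mm)
    if not ptvs:
        raise ValueError("phantom has no targets; nothing to plan")

    intents = partition_intents(ptvs, region_map or DEFAULT_REGION_MAP, prescription)
    goals = build_goal_set(ptvs, prescription)
    all_ptvs = union_all(ptvs, "All_PTVs")
    dose = synthesize_dose(ptvs, phantom.grid, dose_params, prescription,
                           provenance={"plan": "initial"})
    if normalize:
        dose = normalize_dose(dose, all_ptvs)
    return PlanBundle(
        phantom=phantom, ptvs=ptvs, all_ptvs=all_ptvs,
        external=phantom.external_mask, intents=intents, goals=goals,
        dose=dose, prescription=prescription, ptv_margin_mm=ptv_margin_mm,
        normalized=normalize, dose_params=dose_params,
    )


@dataclass
class AdaptiveSession:
    reference_eval: PlanEvaluation
    scheduled_eval: PlanEvaluation
    adapted_eval: PlanEvaluation
    scheduled_available: bool
    availability_reason: str
    selected: str               # "scheduled" | "adapted"
    rationale: str
    change_spec: AnatomyChangeSpec | None = None
    durations: dict[str, float] | None = None


def scheduled_availability(
    evaluation: PlanEvaluation,
    prescription: float,
) -> tuple[bool, str]:
    """Vendor-style hard gate: the scheduled plan is withheld iff any
    target's mean dose is strictly below half the prescription."""
    for name, mean in evaluation.target_mean_dose.items():
        if mean < 0.5 * prescription:
            return False, (
                f"target {name!r} mean dose {mean:.3f} Gy < 50% of "
                f"{prescription:g} Gy prescription"
            )
    return True, "all targets have mean dose >= 50% Rx"


def select_plan(
    scheduled_eval: PlanEvaluation,
    adapted_eval: PlanEvaluation,
    scheduled_available: bool = True,
) -> tuple[str, str]:
    """Lexicographic plan selection: more P1 goals passed wins, then more P2,
    then lower D2cm; an exact tie keeps the scheduled plan (no-adaptation
    default), and an unavailable scheduled plan can never win."""
    if not scheduled_available:
        return "adapted", "scheduled plan unavailable (failed plan-quality gate)"
    for prio in ("P1", "P2"):
        s, a = scheduled_eval.passed(prio), adapted_eval.passed(prio)
        if a != s:
            winner = "adapted" if a > s else "scheduled"
            return winner, f"{winner} passes more {prio} goals ({max(a, s)} vs {min(a, s)})"
    if scheduled_eval.d2cm is not None and adapted_eval.d2cm is not None:
        if abs(adapted_eval.d2cm - scheduled_eval.d2cm) > 1e-9:
            winner = "adapted" if adapted_eval.d2cm < scheduled_eval.d2cm else "scheduled"
            return winner, f"{winner} has lower D2cm"
    return "scheduled", "tie on all criteria; keeping scheduled plan"


def run_session(
    bundle: PlanBundle,
    day: Phantom,
    change_spec: AnatomyChangeSpec | None = None,
    durations: dict[str, float] | None = None,
) -> AdaptiveSession:
    """Simulate one on-couch adaptive session on a day-of phantom.

    Day-of GTVs come from the day phantom's ground-truth lesions; PTVs and
    helper structures are re-derived from the stored rules.  The scheduled
    dose is the initial dose frozen in room coordinates; the adapted dose is
    re-synthesized around the day-of PTVs (re-normalized when the initial
    plan was normalized).  A target that regressed away is simply absent
    from the adapted goal set.
    """
    if not bundle.phantom.grid.same_as(day.grid):
        raise ValueError("day-of phantom must share the planning grid")

    ref_structs = {p.name: p for p in bundle.ptvs}
    reference_eval = evaluate_plan(bundle.dose, ref_structs, bundle.goals,
                                   bundle.all_ptvs, bundle.external)

    _, day_ptvs = _truth_structures(day, bundle.ptv_margin_mm)
    if not day_ptvs:
        raise ValueError("day-of phantom has no remaining targets")
    day_structs = {p.name: p for p in day_ptvs}
    day_goals = build_goal_set(day_ptvs, bundle.prescription)
    day_all = union_all(day_ptvs, "All_PTVs")

    scheduled = recalc_on_anatomy(bundle.dose, day.grid)
    scheduled_eval = evaluate_plan(scheduled, day_structs, day_goals,
                                   day_all, day.external_mask)

    adapted = synthesize_dose(day_ptvs, day.grid, bundle.dose_params,
                              bundle.prescription, provenance={"plan": "adapted"})
    if bundle.normalized:
        adapted = normalize_dose(adapted, day_all)
        if adapted.provenance.get("scaled_by", 1.0) > 1.1:
            warnings.warn(
                "adapted-plan renormalization scaled dose up by more than 10%; "
                "hotspots scale with it",
                stacklevel=2,
            )
    adapted_eval = evaluate_plan(adapted, day_structs, day_goals,
                                 day_all, day.external_mask)

    available, reason = scheduled_availability(scheduled_eval, bundle.prescription)
    if not available:
        scheduled_eval.flags.append("scheduled-unavailable")
    selected, rationale = select_plan(scheduled_eval, adapted_eval, available)
    return AdaptiveSession(
        reference_eval=reference_eval,
        scheduled_eval=scheduled_eval,
        adapted_eval=adapted_eval,
        scheduled_available=available,
        availability_reason=reason,
        selected=selected,
        rationale=rationale,
        change_spec=change_spec,
        durations=durations,
    )


# ---------------------------------------------------------------------------
# workflow timing

@dataclass(frozen=True)
class TimingRecord:
    """Measured step durations (seconds) for one adaptive session/intent."""

    intent_id: str
    n_targets: int
    durations: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(WORKFLOW_STEPS) - set(self.durations)
        if missing:
            raise ValueError(f"missing step durations: {sorted(missing)}")
        if any(v < 0 for v in self.durations.values()):
            raise ValueError("durations must be >= 0")


@dataclass(frozen=True)
class StepFit:
    slope: float        # s per target
    intercept: float    # s
    r_squared: float


@dataclass(frozen=True)
class TimingModel:
    steps: dict[str, StepFit]
    total: StepFit


def _ols(n: np.ndarray, y: np.ndarray) -> StepFit:
    if np.ptp(y) == 0:  # constant durations: flat line, no explained variance
        return StepFit(0.0, float(y.mean()), 0.0)
    res = stats.linregress(n, y)
    return StepFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def fit_timing_model(
    records: list[TimingRecord],
    exclude_outliers: bool = False,
) -> TimingModel:
    """Per-step OLS fit of duration versus number of targets.

    With ``exclude_outliers``, records whose step duration lies more than
    three standard deviations from that step's mean are dropped for that
    step's fit.  The total-duration model is the sum of the step models,
    with its own coefficient of determination measured against the summed
    durations.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 timing records")
    n_all = np.array([r.n_targets for r in records], dtype=float)
    if np.unique(n_all).size < 2:
        raise ValueError("all records have the same target count; slope is unidentifiable")

    steps: dict[str, StepFit] = {}
    for step in WORKFLOW_STEPS:
        y = np.array([r.durations[step] for r in records], dtype=float)
        n = n_all
        if exclude_outliers and y.std(ddof=1) > 0:
            keep = np.abs(y - y.mean()) <= 3.0 * y.std(ddof=1)
            if keep.sum() >= 3 and np.unique(n_all[keep]).size >= 2:
                n, y = n_all[keep], y[keep]
        steps[step] = _ols(n, y)

    slope = sum(f.slope for f in steps.values())
    intercept = sum(f.intercept for f in steps.values())
    totals = np.array([sum(r.durations.values()) for r in records], dtype=float)
    pred = intercept + slope * n_all
    ss_tot = float(((totals - totals.mean()) ** 2).sum())
    ss_res = float(((totals - pred) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return TimingModel(steps, StepFit(slope, intercept, r2))


def predict_session_duration(model: TimingModel, n_targets: int) -> dict[str, float]:
    """Predicted seconds per step plus total, clamped at zero."""
    out: dict[str, float] = {}
    for step, f in model.steps.items():
        v = f.intercept + f.slope * n_targets
        if v < 0:
            warnings.warn(f"negative predicted duration for {step}; clamping to 0",
                          stacklevel=2)
            v = 0.0
        out[step] = v
    out["total"] = sum(out.values())
    return out


#: per-step (intercept s, slope s/target, noise sd s) used by the synthetic
#: timing-log generator; generation steps near-flat, editing/planning rising
#: with target count, echoing the qualitative pattern of measured workflows.
DEFAULT_TIMING_TRUTH: dict[str, tuple[float, float, float]] = {
    "generate_influencers": (70.0, 0.3, 15.0),
    "edit_influencers": (160.0, 1.0, 60.0),
    "generate_targets": (50.0, 7.0, 20.0),
    "edit_targets": (90.0, 45.0, 120.0),
    "generate_plans": (230.0, 12.0, 60.0),
}


def generate_timing_records(
    n_records: int,
    seed: int = 0,
    truth: dict[str, tuple[float, float, float]] | None = None,
    n_targets_range: tuple[int, int] = (1, 25),
) -> list[TimingRecord]:
    """Synthetic timing logs with planted linear structure (for model tests)."""
    truth = truth or DEFAULT_TIMING_TRUTH
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        n = int(rng.integers(n_targets_range[0], n_targets_range[1] + 1))
        durations = {}
        for step in WORKFLOW_STEPS:
            a, b, sd = truth[step]
            durations[step] = max(0.0, a + b * n + sd * rng.standard_normal())
        records.append(TimingRecord(f"intent_{i}", n, durations))
    return records
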