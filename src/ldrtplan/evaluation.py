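"""DVH computation, tiered clinical-goal grading and plan-quality metrics.

The DVH is exact at the voxel level: each voxel contributes its full volume
at its dose, with no sub-voxel interpolation.  Volume queries at a plateau
return the step value at the requested cumulative volume, with exact-boundary
ties resolved toward the conservative side (colder for near-minimum queries,
hotter for near-maximum queries).

Plan-quality metrics follow the usual conformality definitions for a
prescription Rx and the combined target volume V_PTV:

* ``R50%`` = volume receiving >= 0.5·Rx divided by V_PTV (dose spill),
* ``CI``   = volume receiving >= Rx divided by V_PTV (ideal 1.0),
* ``D2cm`` = maximum dose at >= 2 cm from any PTV, as % of Rx.

Isodose volumes for R50%/CI are measured over the whole grid; the D2cm
search region is restricted to the external (body) contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .core import StructureMask, _require_same_grid
from .plangeom import ClinicalGoal
from .structures import distance_map

if TYPE_CHECKING:  # pragma: no cover
    from .dose import DoseGrid

__all__ = [
    "DVHCurve",
    "GoalResult",
    "ConformalityMetrics",
    "PlanEvaluation",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "grade_goals",
    "conformality_metrics",
    "evaluate_plan",
    "summarize_cohort",
]


@dataclass(frozen=True)
class DVHCurve:
    """Exact voxel-list dose-volume data for one structure."""

    structure: str
    doses: np.ndarray          # sorted ascending, Gy
    voxel_volume_cc: float

    @property
    def total_volume_cc(self) -> float:
        return self.doses.size * self.voxel_volume_cc

    @property
    def mean_dose(self) -> float:
        return float(self.doses.mean())


def compute_dvh(dose: "DoseGrid", mask: StructureMask) -> DVHCurve:
    if mask.is_empty():
        raise ValueError(f"cannot compute DVH of empty structure {mask.name!r}")
    _require_same_grid(dose.dose.grid, mask.grid, "dose and structure")
    vals = np.sort(dose.dose.values[mask.mask].astype(float))
    return DVHCurve(mask.name, vals, mask.grid.voxel_volume_cc)


def dose_at_volume(dvh: DVHCurve, v_cc: float, from_end: str = "cold") -> float:
    """Dose (Gy) at cumulative volume ``v_cc`` from the cold or hot end.

    ``from_end="cold"`` gives near-minimum queries (Dmin to all but v_cc);
    ``"hot"`` gives near-maximum queries (dose to the hottest v_cc).
    """
    if not 0 < v_cc <= dvh.total_volume_cc + 1e-12:
        raise ValueError(
            f"v_cc must be in (0, {dvh.total_volume_cc:.4g}] cc, got {v_cc}"
        )
    n = dvh.doses.size
    cum = (np.arange(n) + 1) * dvh.voxel_volume_cc
    idx = int(np.searchsorted(cum, v_cc - 1e-12, side="left"))
    idx = min(idx, n - 1)
    if from_end == "cold":
        return float(dvh.doses[idx])
    if from_end == "hot":
        return float(dvh.doses[n - 1 - idx])
    raise ValueError(f"from_end must be 'cold' or 'hot', got {from_end!r}")


def volume_at_dose(dvh: DVHCurve, d: float) -> float:
    """Percent of the structure volume receiving at least ``d`` Gy."""
    n = dvh.doses.size
    covered = n - int(np.searchsorted(dvh.doses, d - 1e-12, side="left"))
    return 100.0 * covered / n


@dataclass(frozen=True)
class GoalResult:
    goal: ClinicalGoal
    achieved_value: float
    grade: str  # "pass" | "variation" | "fail"


def _achieved(dvh: DVHCurve, goal: ClinicalGoal) -> float:
    if goal.metric == "V":
        return volume_at_dose(dvh, goal.dose)
    if goal.metric == "Dmin_cc":
        return dose_at_volume(dvh, goal.volume_cc, "cold")
    if goal.metric == "Dmax_cc":
        return dose_at_volume(dvh, goal.volume_cc, "hot")
    return dvh.mean_dose


def _grade(goal: ClinicalGoal, achieved: float) -> str:
    # non-strict comparisons get a tiny relative slack so a value that equals
    # the limit up to float rounding (e.g. after exact normalization) passes;
    # strict goals ("< 0.5 Gy") compare exactly, so equality does not pass
    eps = 1e-9 * max(1.0, abs(goal.threshold))

    def meets(limit: float) -> bool:
        if goal.direction == "ge":
            return achieved > limit if goal.strict else achieved >= limit - eps
        return achieved < limit if goal.strict else achieved <= limit + eps

    if meets(goal.threshold):
        return "pass"
    if goal.variation is not None and meets(goal.variation):
        return "variation"
    return "fail"


def grade_goals(
    dose: "DoseGrid",
    structures: dict[str, StructureMask],
    goals: Iterable[ClinicalGoal],
) -> list[GoalResult]:
    """Grade each goal as pass / variation / fail from the exact DVH.

    A goal whose structure is present but empty (e.g. a target that vanished
    at adaptation) cannot be evaluated and raises; absent structures raise
    with the missing name.
    """
    dvhs: dict[str, DVHCurve] = {}
    results = []
    for goal in goals:
        if goal.structure not in structures:
            raise KeyError(f"goal references missing structure {goal.structure!r}")
        if goal.structure not in dvhs:
            dvhs[goal.structure] = compute_dvh(dose, structures[goal.structure])
        achieved = _achieved(dvhs[goal.structure], goal)
        results.append(GoalResult(goal, achieved, _grade(goal, achieved)))
    return results


@dataclass(frozen=True)
class ConformalityMetrics:
    r50: float
    ci: float
    d2cm_pct: float


def conformality_metrics(
    dose: "DoseGrid",
    all_ptvs: StructureMask,
    external: StructureMask,
    prescription: float | None = None,
) -> ConformalityMetrics:
    if all_ptvs.is_empty() or external.is_empty():
        raise ValueError("conformality metrics need non-empty target and body structures")
    rx = dose.prescription if prescription is None else prescription
    vals = dose.dose.values
    vox = all_ptvs.grid.voxel_volume_cc
    v_ptv = all_ptvs.volume_cc
    r50 = float((vals >= 0.5 * rx).sum()) * vox / v_ptv
    ci = float((vals >= rx).sum()) * vox / v_ptv
    far = external.mask & (distance_map(all_ptvs).values >= 20.0)
    if not far.any():
        raise ValueError("no body voxel lies >= 2 cm from the targets; D2cm undefined")
    d2cm = 100.0 * float(vals[far].max()) / rx
    return ConformalityMetrics(r50, ci, d2cm)


@dataclass
class PlanEvaluation:
    """Per-structure goal grades plus plan-level conformality for one plan."""

    goal_results: list[GoalResult]
    r50: float | None = None
    ci: float | None = None
    d2cm: float | None = None
    pct_goals_met: dict[str, float] = field(default_factory=dict)
    target_mean_dose: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def passed(self, priority: str) -> int:
        return sum(1 for r in self.goal_results
                   if r.goal.priority == priority and r.grade == "pass")

    def n_goals(self, priority: str) -> int:
        return sum(1 for r in self.goal_results if r.goal.priority == priority)


def _goal_kind(goal: ClinicalGoal) -> str:
    """Goal identity independent of the structure it applies to."""
    return goal.describe().split(" ", 1)[1]


def evaluate_plan(
    dose: "DoseGrid",
    structures: dict[str, StructureMask],
    goals: Iterable[ClinicalGoal],
    all_ptvs: StructureMask | None = None,
    external: StructureMask | None = None,
) -> PlanEvaluation:
    """Grade goals and, when target/body structures are given, compute the
    R50%/CI/D2cm conformality metrics and per-kind goal attainment."""
    goals = list(goals)
    results = grade_goals(dose, structures, goals)
    ev = PlanEvaluation(goal_results=results)
    kinds: dict[str, list[str]] = {}
    for r in results:
        kinds.setdefault(_goal_kind(r.goal), []).append(r.grade)
    ev.pct_goals_met = {
        k: 100.0 * sum(g == "pass" for g in grades) / len(grades)
        for k, grades in kinds.items()
    }
    target_names = {g.structure for g in goals}
    for name in sorted(target_names):
        mask = structures[name]
        if not mask.is_empty() and mask.role in ("PTV", "GTV", "helper"):
            ev.target_mean_dose[name] = float(dose.dose.values[mask.mask].mean())
    if all_ptvs is not None and external is not None:
        m = conformality_metrics(dose, all_ptvs, external)
        ev.r50, ev.ci, ev.d2cm = m.r50, m.ci, m.d2cm_pct
    return ev


def summarize_cohort(
    evaluations: list[PlanEvaluation],
    plan_types: list[str],
) -> pd.DataFrame:
    """Cohort table: per plan type and goal kind, the mean ± sample sd of the
    per-plan percentage of structures achieving the goal.

    A goal kind absent from every plan of a type is reported as NaN
    (not applicable), never as 0.
    """
    if not evaluations:
        raise ValueError("need at least one evaluation")
    if len(plan_types) != len(evaluations):
        raise ValueError("one plan-type label per evaluation required")
    rows = []
    for ev, label in zip(evaluations, plan_types):
        for kind, pct in ev.pct_goals_met.items():
            rows.append({"plan_type": label, "goal": kind, "pct": pct})
        if ev.r50 is not None:
            rows.append({"plan_type": label, "goal": "R50%", "pct": ev.r50})
            rows.append({"plan_type": label, "goal": "CI", "pct": ev.ci})
            rows.append({"plan_type": label, "goal": "D2cm [%]", "pct": ev.d2cm})
    df = pd.DataFrame(rows)
    out = df.groupby(["goal", "plan_type"])["pct"].agg(["mean", "std", "count"])
    return out.unstack("plan_type")
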