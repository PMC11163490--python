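"""Planning geometry for widespread (polymetastatic) target distributions.

Two planning styles are covered:

* **Conventional multi-isocenter sectioning** — the treated region (most
  superior to most inferior PTV extent, plus 1 cm on each end) is divided
  into N = ceil(C / 22 cm) equal sections, one isocenter per section at the
  section's superior-inferior midpoint; 22 cm is a conservative working
  length under the machine's 28 cm maximum field size.  Lateral and
  anterior-posterior isocenter coordinates sit at the centroid of all PTVs so
  only couch in/out shifts are needed between isocenters.

* **RT-intent partitioning** — targets are grouped into independently
  optimized planning units ("RT intents"), each limited to a combined target
  length of 26 cm with one isocenter or 38.5 cm with two.  Intent boundaries
  start from an equal division and are shifted into target-free gaps so no
  target straddles two intents; adjacent targets in different intents closer
  than 5 mm are flagged as junctions, and dedicated junction helper
  structures with dose-gradient goals are derived for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import StructureMask
from .structures import MarginSpec, combine, expand, union_all

__all__ = [
    "SectioningResult",
    "CoverageReport",
    "ClinicalGoal",
    "RTIntent",
    "PlanTemplate",
    "JunctionFlag",
    "JunctionStructures",
    "compute_sectioning",
    "coverage_check",
    "partition_intents",
    "detect_junctions",
    "derive_junction_structures",
    "assign_plan_template",
    "summarize_plan_geometry",
    "build_goal_set",
    "INFLUENCERS",
]

#: conservative per-isocenter section length (mm) under the 28 cm field limit
SECTION_LENGTH_MM = 220.0
#: physical maximum field length (mm); half-length bounds voxel-to-isocenter SI distance
MAX_FIELD_LENGTH_MM = 280.0
#: superior/inferior margin (mm) added beyond PTV extremes for field coverage
END_MARGIN_MM = 10.0
#: combined-target length limits (mm) for 1 and 2 isocenters per RT intent
INTENT_LIMIT_1ISO_MM = 260.0
INTENT_LIMIT_2ISO_MM = 385.0

#: anatomical region -> influencer organs used for structure-guided propagation
INFLUENCERS: dict[str, tuple[str, ...]] = {
    "thorax": ("esophagus", "heart", "lung_left", "lung_right", "trachea"),
    "abdomen": ("duodenum", "liver", "pancreas", "stomach"),
    "pelvis": ("bladder", "rectum"),
    "extremity": (),
}

IMRT_FIELD_MENU = (7, 9, 12)
VMAT_ARC_MENU = (2, 3)
LATERAL_IMRT_FIELDS = 7
LATERAL_VMAT_ARCS = 2

PRIORITIES = ("P1", "P2", "P3", "P4", "R")


# ---------------------------------------------------------------------------
# clinical goals

@dataclass(frozen=True)
class ClinicalGoal:
    """A DVH-based planning goal with an acceptable-variation fallback.

    ``metric``: ``V`` (percent of volume receiving >= ``dose`` Gy),
    ``Dmin_cc`` (minimum dose to all but the coldest ``volume_cc``),
    ``Dmax_cc`` (dose to the hottest ``volume_cc``), or ``Dmean``.
    ``threshold``/``variation`` are in % for V metrics and Gy otherwise;
    the variation is never stricter than the threshold.
    """

    structure: str
    metric: str
    threshold: float
    direction: str  # "ge" or "le"
    priority: str
    dose: float | None = None        # Gy, for V metrics
    volume_cc: float | None = None   # cc, for Dmin_cc / Dmax_cc
    variation: float | None = None
    strict: bool = False             # strict inequality (e.g. "< 0.5 Gy")

    def __post_init__(self) -> None:
        if self.metric not in ("V", "Dmin_cc", "Dmax_cc", "Dmean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.direction not in ("ge", "le"):
            raise ValueError(f"direction must be 'ge' or 'le', got {self.direction!r}")
        if self.priority not in PRIORITIES:
            raise ValueError(f"priority must be one of {PRIORITIES}, got {self.priority!r}")
        if self.metric == "V" and self.dose is None:
            raise ValueError("V metric requires a dose level")
        if self.metric in ("Dmin_cc", "Dmax_cc") and self.volume_cc is None:
            raise ValueError(f"{self.metric} requires volume_cc")
        if self.variation is not None:
            if self.direction == "ge" and self.variation > self.threshold:
                raise ValueError("variation stricter than threshold (ge goal)")
            if self.direction == "le" and self.variation < self.threshold:
                raise ValueError("variation stricter than threshold (le goal)")

    def describe(self) -> str:
        if self.metric == "V":
            head = f"V_{self.dose:g}Gy"
        elif self.metric == "Dmean":
            head = "Dmean"
        else:
            kind = "min," if self.metric == "Dmin_cc" else ""
            head = f"D{kind}{self.volume_cc:g}cc"
        op = {"ge": ">=", "le": "<="}[self.direction]
        if self.strict:
            op = {"ge": ">", "le": "<"}[self.direction]
        unit = "%" if self.metric == "V" else " Gy"
        return f"{self.structure} {head} {op} {self.threshold:g}{unit} ({self.priority})"


def build_goal_set(
    targets: list[StructureMask] | list[str],
    prescription: float = 1.0,
    normal_goals: list[ClinicalGoal] | None = None,
) -> list[ClinicalGoal]:
    """Per-PTV coverage/homogeneity goals at the two highest priorities.

    For each target: V_Rx >= 95 % (variation 90 %) at P1, near-minimum dose
    Dmin,0.03cc >= 0.95·Rx (variation 0.90·Rx) at P1, and near-maximum dose
    D0.03cc <= 1.20·Rx (variation 1.25·Rx) at P2.  Dose-valued thresholds
    scale with the prescription; percent goals do not.  Normal-tissue goals
    (P3/P4) are appended from ``normal_goals`` when supplied.
    """
    if not targets:
        raise ValueError("need at least one target")
    names = [t.name if isinstance(t, StructureMask) else str(t) for t in targets]
    goals: list[ClinicalGoal] = []
    for name in names:
        goals.append(ClinicalGoal(name, "V", 95.0, "ge", "P1", dose=prescription,
                                  variation=90.0))
        goals.append(ClinicalGoal(name, "Dmin_cc", 0.95 * prescription, "ge", "P1",
                                  volume_cc=0.03, variation=0.90 * prescription))
        goals.append(ClinicalGoal(name, "Dmax_cc", 1.20 * prescription, "le", "P2",
                                  volume_cc=0.03, variation=1.25 * prescription))
    if normal_goals:
        for g in normal_goals:
            if g.priority not in ("P3", "P4", "R"):
                raise ValueError("normal-tissue goals must be P3/P4/R")
            goals.append(g)
    return goals


# ---------------------------------------------------------------------------
# conventional sectioning

@dataclass(frozen=True)
class SectioningResult:
    """Multi-isocenter sectioning of the treated region.

    ``A``/``B`` are the superior/inferior borders (PTV extremes ± 1 cm),
    ``C = A − B`` the total length, ``N = ceil(C / 220 mm)`` the isocenter
    count, ``D = C / N`` the section length.  ``section_limits`` holds the
    inferior limit of each section moving inferiorly (last equals B);
    ``isocenters`` the (x, y, z) positions, all sharing the lateral/AP
    centroid of the combined PTV voxel set, z at each section's midpoint.
    """

    A: float
    B: float
    C: float
    N: int
    D: float
    section_limits: tuple[float, ...]
    isocenters: tuple[tuple[float, float, float], ...]


def _si_extents(ptvs: list[StructureMask]) -> list[tuple[float, float]]:
    return [p.extent_mm(2) for p in ptvs]


def compute_sectioning(ptvs: list[StructureMask]) -> SectioningResult:
    if not ptvs:
        raise ValueError("need at least one PTV")
    extents = _si_extents(ptvs)
    A = max(hi for _, hi in extents) + END_MARGIN_MM
    B = min(lo for lo, _ in extents) - END_MARGIN_MM
    C = A - B
    N = max(1, math.ceil(C / SECTION_LENGTH_MM - 1e-12))
    D = C / N
    limits = tuple(A - (n + 1) * D for n in range(N))
    all_ptvs = union_all(ptvs)
    cx, cy, _ = all_ptvs.centroid_mm()
    isocenters = tuple((float(cx), float(cy), A - n * D - D / 2.0) for n in range(N))
    return SectioningResult(A, B, C, N, D, limits, isocenters)


@dataclass
class CoverageReport:
    """Field-length coverage audit for a sectioning layout."""

    violations: list[str]
    worst_margin_mm: float          # 140 mm minus the worst section half-length
    max_voxel_offset_mm: float      # worst PTV-voxel SI distance to its isocenter

    @property
    def ok(self) -> bool:
        return not self.violations


def coverage_check(sectioning: SectioningResult, ptvs: list[StructureMask]) -> CoverageReport:
    """Verify every PTV voxel lies within half the maximum field length
    (140 mm) of its section's isocenter.  Violations are reported, not raised."""
    half = MAX_FIELD_LENGTH_MM / 2.0
    violations: list[str] = []
    if sectioning.D / 2.0 + 1e-9 > half:
        violations.append(
            f"section half-length {sectioning.D / 2:.1f} mm exceeds field half-length {half:.0f} mm"
        )
    max_offset = 0.0
    iso_z = np.array([iso[2] for iso in sectioning.isocenters])
    for ptv in ptvs:
        zidx = np.unique(np.argwhere(ptv.mask)[:, 2])
        zs = ptv.grid.coords(2)[zidx]
        # section of a voxel: the interval [A-(n+1)D, A-nD] containing its z
        sec = np.clip(np.floor((sectioning.A - zs) / sectioning.D).astype(int),
                      0, sectioning.N - 1)
        off = np.abs(zs - iso_z[sec])
        worst = float(off.max()) if off.size else 0.0
        max_offset = max(max_offset, worst)
        if worst > half + 1e-9:
            violations.append(
                f"PTV {ptv.name!r} has voxels {worst:.1f} mm SI from its isocenter (> {half:.0f} mm)"
            )
    return CoverageReport(violations, half - sectioning.D / 2.0, max_offset)


# ---------------------------------------------------------------------------
# RT-intent partitioning

@dataclass
class PlanTemplate:
    modality: str                 # "IMRT" | "VMAT"
    fields_per_isocenter: int     # IMRT fields or VMAT arcs per isocenter
    lateralized: bool = False


@dataclass
class RTIntent:
    """An independently optimized planning unit (prescription + structures +
    goals + plan), limited to at most two co-optimized isocenters."""

    region: str
    target_ids: list[str]
    si_range: tuple[float, float]       # (inferior, superior) target extent, mm
    isocenter_count: int
    influencers: tuple[str, ...] = ()
    goals: list[ClinicalGoal] = field(default_factory=list)
    plan_template: PlanTemplate | None = None
    normalization: str | None = None
    sectioning: SectioningResult | None = None

    @property
    def target_span_mm(self) -> float:
        return self.si_range[1] - self.si_range[0]

    @property
    def total_fields(self) -> int:
        if self.plan_template is None:
            return 0
        return self.plan_template.fields_per_isocenter * self.isocenter_count


def _merged_blocks(extents: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping/abutting SI intervals into disjoint blocks."""
    blocks: list[list[float]] = []
    for lo, hi in sorted(extents):
        if blocks and lo <= blocks[-1][1]:
            blocks[-1][1] = max(blocks[-1][1], hi)
        else:
            blocks.append([lo, hi])
    return [(lo, hi) for lo, hi in blocks]


def _adjust_boundary(b: float, blocks: list[tuple[float, float]]) -> float:
    """Shift a boundary out of any target block it cuts.

    Candidate landing spots are the target-free gaps between blocks; of the
    two gaps adjacent to the cut block the larger wins (tie: superior), and
    the boundary lands at the gap midpoint.  With no free gap the boundary is
    left in place (targets are then assigned by centroid and any close pair
    across the boundary surfaces via junction detection).
    """
    inside = next(((lo, hi) for lo, hi in blocks if lo < b < hi), None)
    if inside is None:
        return b
    gaps: list[tuple[float, float]] = []
    for (lo1, hi1), (lo2, hi2) in zip(blocks, blocks[1:]):
        if lo2 > hi1:
            gaps.append((hi1, lo2))
    if not gaps:
        return b
    below = [g for g in gaps if g[1] <= inside[0]]
    above = [g for g in gaps if g[0] >= inside[1]]
    candidates = []
    if below:
        candidates.append(max(below, key=lambda g: g[0]))   # nearest below
    if above:
        candidates.append(min(above, key=lambda g: g[0]))   # nearest above
    # larger gap wins; tie broken toward the superior gap
    best = max(candidates, key=lambda g: (g[1] - g[0], g[0]))
    return (best[0] + best[1]) / 2.0


def _isocenter_count(span: float) -> int:
    if span <= INTENT_LIMIT_1ISO_MM:
        return 1
    if span <= INTENT_LIMIT_2ISO_MM:
        return 2
    raise ValueError(f"target span {span:.1f} mm exceeds the 2-isocenter limit "
                     f"of {INTENT_LIMIT_2ISO_MM:.0f} mm")


def region_for(z: float, region_map: list[tuple[float, float, str]]) -> str:
    """Label for an SI position from a (z_min, z_max, region) table."""
    for lo, hi, label in region_map:
        if lo <= z <= hi:
            return label
    raise ValueError(f"no region defined at z = {z:.1f} mm")


def partition_intents(
    ptvs: list[StructureMask],
    region_map: list[tuple[float, float, str]],
    prescription: float = 1.0,
) -> list[RTIntent]:
    """Group targets into RT intents respecting the per-intent length limits.

    The A..B span (target extremes ± 1 cm) is divided into
    ceil(C / 385 mm) equal sections; each boundary is shifted into a
    target-free gap so no target straddles two intents; targets are assigned
    by SI position; each group gets the minimal isocenter count for its span
    (1 if <= 260 mm, 2 if <= 385 mm), a region label from ``region_map`` at
    the span midpoint, the region's influencer organs, and per-target goals.
    A group still exceeding 385 mm is re-partitioned on its own.  Output is
    ordered inferior to superior.

    Raises
    ------
    ValueError
        If a single target is longer than 385 mm (cannot fit any intent).
    """
    if not ptvs:
        raise ValueError("need at least one PTV")
    extents = _si_extents(ptvs)
    for ptv, (lo, hi) in zip(ptvs, extents):
        if hi - lo > INTENT_LIMIT_2ISO_MM:
            raise ValueError(
                f"PTV {ptv.name!r} spans {hi - lo:.1f} mm, longer than the "
                f"{INTENT_LIMIT_2ISO_MM:.0f} mm 2-isocenter intent limit"
            )
    A = max(hi for _, hi in extents) + END_MARGIN_MM
    B = min(lo for lo, _ in extents) - END_MARGIN_MM
    C = A - B
    M = max(1, math.ceil(C / INTENT_LIMIT_2ISO_MM - 1e-12))
    blocks = _merged_blocks(extents)
    boundaries = sorted(
        {_adjust_boundary(A - k * C / M, blocks) for k in range(1, M)}
    )

    groups: list[list[int]] = [[] for _ in range(len(boundaries) + 1)]
    for i, (lo, hi) in enumerate(extents):
        mid = (lo + hi) / 2.0
        k = int(np.searchsorted(boundaries, mid))
        groups[k].append(i)

    intents: list[RTIntent] = []
    for group in groups:
        if not group:
            continue
        span_lo = min(extents[i][0] for i in group)
        span_hi = max(extents[i][1] for i in group)
        span = span_hi - span_lo
        members = [ptvs[i] for i in group]
        if span > INTENT_LIMIT_2ISO_MM and len(members) > 1:
            sub = partition_intents(members, region_map, prescription)
            if len(sub) > 1:
                intents.extend(sub)
                continue
            raise ValueError(
                f"cannot split target group spanning {span:.1f} mm: no target-free gap"
            )
        n_iso = _isocenter_count(span)
        region = region_for((span_lo + span_hi) / 2.0, region_map)
        intent = RTIntent(
            region=region,
            target_ids=[m.name for m in members],
            si_range=(span_lo, span_hi),
            isocenter_count=n_iso,
            influencers=INFLUENCERS.get(region, ()),
            goals=build_goal_set(members, prescription),
            sectioning=compute_sectioning(members) if n_iso > 1 else None,
        )
        intents.append(intent)
    intents.sort(key=lambda it: it.si_range[0])
    return intents


@dataclass(frozen=True)
class JunctionFlag:
    intent_a: int       # index of the intent holding target_a
    intent_b: int
    target_a: str
    target_b: str
    gap_mm: float


def detect_junctions(
    intents: list[RTIntent],
    ptvs: list[StructureMask],
    gap_threshold_mm: float = 5.0,
) -> list[JunctionFlag]:
    """Flag pairs of targets in *different* intents separated by less than
    ``gap_threshold_mm`` in the superior-inferior direction (overlapping SI
    projections count as gap <= 0)."""
    if len(intents) < 2:
        return []
    by_name = {p.name: p for p in ptvs}
    owner = {tid: k for k, it in enumerate(intents) for tid in it.target_ids}
    flags: list[JunctionFlag] = []
    names = [p.name for p in ptvs if p.name in owner]
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            if owner[na] == owner[nb]:
                continue
            alo, ahi = by_name[na].extent_mm(2)
            blo, bhi = by_name[nb].extent_mm(2)
            gap = max(blo - ahi, alo - bhi)
            if gap < gap_threshold_mm:
                a, b = (na, nb) if ahi >= bhi else (nb, na)
                flags.append(JunctionFlag(owner[a], owner[b], a, b, float(gap)))
    flags.sort(key=lambda f: (f.gap_mm, f.target_a))
    return flags


@dataclass
class JunctionStructures:
    """Helper structures and goals shaping the dose gradient at an intent
    junction (superior target a, inferior target b)."""

    ptv_a_opti: StructureMask
    junction_avoid: StructureMask
    extra_goals: list[ClinicalGoal]


def derive_junction_structures(
    ptv_a: StructureMask,
    ptv_b: StructureMask,
    prescription: float = 1.0,
    lateral_ap_mm: float = 30.0,
    si_crop_mm: float = 5.0,
    avoid_band_mm: float = 3.0,
) -> JunctionStructures:
    """Derive the junction helpers for two adjacent targets in different
    intents (``ptv_a`` superior, ``ptv_b`` inferior; caller orients).

    * ``PTV_a_Opti`` = PTV_a minus PTV_b expanded 3 cm laterally/AP and
      0.5 cm toward head and feet — the optimization target is pulled 0.5 cm
      off the neighbour so each intent's falloff lands between them.
    * ``Junction_avoid`` = a 0.3 cm band immediately inferior to PTV_a's
      3 cm lateral/AP expansion, where the composite hotspot would form.
    * ``extra_goals``: the Table-1-style coverage goals transferred to
      PTV_a_Opti with the hotspot bound tightened to the prescription, dose
      limits on PTV_b as an avoidance structure (D0.03cc < 0.5 Gy and
      V_1Gy < 2 %, both P4), and Junction_avoid V_2Gy <= 10 % (P2).

    Everything is derived from the PTVs alone, so the helpers re-derive
    automatically when the anatomy (and hence the PTVs) changes.
    """
    if ptv_a.is_empty() or ptv_b.is_empty():
        raise ValueError("junction PTVs must be non-empty")
    b_exp = expand(ptv_b, MarginSpec.lateral_ap_si(lateral_ap_mm, si_crop_mm, si_crop_mm))
    opti = combine(ptv_a, b_exp, "subtract", f"{ptv_a.name}_Opti")
    opti.role = "helper"

    a_exp_band = expand(ptv_a, MarginSpec.lateral_ap_si(lateral_ap_mm, 0.0, avoid_band_mm))
    a_exp_flat = expand(ptv_a, MarginSpec.lateral_ap_si(lateral_ap_mm, 0.0, 0.0))
    avoid = combine(a_exp_band, a_exp_flat, "subtract", "Junction_avoid")
    avoid.role = "helper"

    rx = prescription
    extra_goals = [
        ClinicalGoal(opti.name, "V", 95.0, "ge", "P1", dose=rx, variation=90.0),
        ClinicalGoal(opti.name, "Dmin_cc", 0.95 * rx, "ge", "P1", volume_cc=0.03,
                     variation=0.90 * rx),
        ClinicalGoal(opti.name, "Dmax_cc", 1.0 * rx, "le", "P2", volume_cc=0.03),
        ClinicalGoal(ptv_b.name, "Dmax_cc", 0.5 * rx, "le", "P4", volume_cc=0.03,
                     strict=True),
        ClinicalGoal(ptv_b.name, "V", 2.0, "le", "P4", dose=rx, strict=True),
        ClinicalGoal(avoid.name, "V", 10.0, "le", "P2", dose=2.0 * rx),
    ]
    return JunctionStructures(opti, avoid, extra_goals)


def assign_plan_template(
    intent: RTIntent,
    modality: str = "IMRT",
    count: int | None = None,
    lateralized: bool = False,
) -> RTIntent:
    """Attach a delivery template: 7/9/12 equally spaced fixed-field IMRT or
    2/3 full-arc VMAT per isocenter; lateralized targets additionally allow a
    7-lateral-field IMRT or 2-partial-arc VMAT variant.  IMRT is the default
    modality (it produced the higher plan quality in this workflow)."""
    if modality == "IMRT":
        menu = IMRT_FIELD_MENU if not lateralized else IMRT_FIELD_MENU + (LATERAL_IMRT_FIELDS,)
        if count is None:
            count = 9
    elif modality == "VMAT":
        menu = VMAT_ARC_MENU if not lateralized else VMAT_ARC_MENU + (LATERAL_VMAT_ARCS,)
        if count is None:
            count = 2
    else:
        raise ValueError(f"modality must be IMRT or VMAT, got {modality!r}")
    if count not in menu:
        raise ValueError(f"{modality} count {count} not in allowed menu {sorted(set(menu))}")
    intent.plan_template = PlanTemplate(modality, count, lateralized)
    return intent


@dataclass
class PlanGeometrySummary:
    table: pd.DataFrame
    total_fields: int
    total_isocenters: int
    total_targets: int


def summarize_plan_geometry(intents: list[RTIntent]) -> PlanGeometrySummary:
    """Per-intent and total field/isocenter/target bookkeeping."""
    rows = []
    for it in intents:
        rows.append({
            "region": it.region,
            "targets": len(it.target_ids),
            "isocenters": it.isocenter_count,
            "modality": it.plan_template.modality if it.plan_template else None,
            "fields_per_isocenter": (
                it.plan_template.fields_per_isocenter if it.plan_template else 0
            ),
            "fields": it.total_fields,
            "span_mm": round(it.target_span_mm, 1),
        })
    table = pd.DataFrame(rows, columns=["region", "targets", "isocenters", "modality",
                                        "fields_per_isocenter", "fields", "span_mm"])
    return PlanGeometrySummary(
        table=table,
        total_fields=int(table["fields"].sum()) if rows else 0,
        total_isocenters=int(table["isocenters"].sum()) if rows else 0,
        total_targets=int(table["targets"].sum()) if rows else 0,
    )
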