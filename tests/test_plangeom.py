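"""Sectioning, intent partitioning, junction derivation and goal sets."""

import math

import numpy as np
import pytest

from ldrtplan.core import StructureMask
from ldrtplan.plangeom import (
    ClinicalGoal,
    assign_plan_template,
    build_goal_set,
    compute_sectioning,
    coverage_check,
    derive_junction_structures,
    detect_junctions,
    partition_intents,
    summarize_plan_geometry,
)
from ldrtplan.presets import three_region_targets

from conftest import box_mask, make_grid


def si_box(grid, z_lo, z_hi, name="PTV", x=(20.0, 40.0), y=(20.0, 40.0)):
    return box_mask(grid, (x[0], y[0], z_lo), (x[1], y[1], z_hi), name, role="PTV")


@pytest.fixture
def long_grid():
    # 1 mm SI spacing so mask extents land exactly on integer mm
    return make_grid((16, 16, 600), (4.0, 4.0, 1.0))


class TestSectioning:
    def test_single_short_target(self, long_grid):
        ptv = si_box(long_grid, 100.0, 140.0)  # spans 40 mm
        sec = compute_sectioning([ptv])
        assert sec.A == 150.0 and sec.B == 90.0 and sec.C == 60.0
        assert sec.N == 1 and sec.D == 60.0
        assert sec.isocenters[0][2] == pytest.approx(120.0)  # PTV SI midpoint
        assert sec.section_limits == (90.0,)

    def test_two_section_split(self, long_grid):
        ptvs = [si_box(long_grid, 50.0, 80.0, "lo"), si_box(long_grid, 400.0, 470.0, "hi")]
        sec = compute_sectioning(ptvs)
        assert sec.C == 440.0 and sec.N == 2 and sec.D == 220.0
        assert sec.isocenters[0][2] == pytest.approx(sec.A - 110.0)
        assert sec.isocenters[1][2] == pytest.approx(sec.A - 330.0)

    def test_exact_boundary_stays_single_section(self, long_grid):
        ptv = si_box(long_grid, 100.0, 300.0)  # C = 220 exactly
        sec = compute_sectioning([ptv])
        assert sec.C == 220.0 and sec.N == 1 and sec.D == 220.0

    def test_lateral_ap_at_combined_centroid(self, long_grid):
        a = si_box(long_grid, 50.0, 70.0, "a", x=(8.0, 16.0))
        b = si_box(long_grid, 90.0, 110.0, "b", x=(40.0, 48.0))
        sec = compute_sectioning([a, b])
        from ldrtplan.structures import union_all
        cx, cy, _ = union_all([a, b]).centroid_mm()
        for iso in sec.isocenters:
            assert iso[0] == pytest.approx(cx) and iso[1] == pytest.approx(cy)

    def test_randomized_sets_match_formula_oracle(self, long_grid):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = rng.integers(1, 7)
            ptvs = []
            for i in range(n):
                z0 = float(rng.uniform(5, 500))
                ptvs.append(si_box(long_grid, z0, min(z0 + float(rng.uniform(5, 80)), 595.0),
                                   f"p{i}"))
            sec = compute_sectioning(ptvs)
            extents = [p.extent_mm(2) for p in ptvs]
            A = max(h for _, h in extents) + 10.0
            B = min(l for l, _ in extents) - 10.0
            C = A - B
            N = math.ceil(C / 220.0 - 1e-12)
            assert (sec.A, sec.B, sec.C, sec.N) == (A, B, C, N)
            assert sec.D == pytest.approx(C / N)
            for k, iso in enumerate(sec.isocenters):
                assert iso[2] == pytest.approx(A - k * sec.D - sec.D / 2.0)
            assert coverage_check(sec, ptvs).ok

    def test_coverage_check_flags_overlong_section(self, long_grid):
        from dataclasses import replace

        ptv = si_box(long_grid, 50.0, 560.0)
        with pytest.raises(ValueError):
            # a >385 mm single target cannot be partitioned, but sectioning allows it
            partition_intents([ptv], [(-1e9, 1e9, "abdomen")])
        sec = compute_sectioning([ptv])
        forced = replace(sec, N=1, D=sec.C, section_limits=(sec.B,),
                         isocenters=((0.0, 0.0, (sec.A + sec.B) / 2.0),))
        report = coverage_check(forced, [ptv])
        assert not report.ok and report.worst_margin_mm < 0

    def test_single_target_worst_margin(self, long_grid):
        ptv = si_box(long_grid, 100.0, 140.0)
        report = coverage_check(compute_sectioning([ptv]), [ptv])
        # 140 - (half target length + 10 mm end margin)
        assert report.worst_margin_mm == pytest.approx(140.0 - (20.0 + 10.0))


class TestPartitioning:
    def test_worked_31_target_three_regions(self):
        ptvs, region_map = three_region_targets()
        intents = partition_intents(ptvs, region_map)
        assert [it.region for it in intents] == ["pelvis", "abdomen", "thorax"]
        assert [it.isocenter_count for it in intents] == [1, 1, 2]
        assert sum(len(it.target_ids) for it in intents) == 31
        thorax = intents[-1]
        assert thorax.target_span_mm > 260.0
        assert thorax.influencers == ("esophagus", "heart", "lung_left",
                                      "lung_right", "trachea")

    def test_compact_distribution_single_intent(self, long_grid):
        ptvs = [si_box(long_grid, 100.0 + 30 * i, 120.0 + 30 * i, f"p{i}") for i in range(4)]
        intents = partition_intents(ptvs, [(-1e9, 1e9, "pelvis")])
        assert len(intents) == 1
        assert intents[0].isocenter_count == 1
        assert intents[0].influencers == ("bladder", "rectum")

    def test_no_target_straddles_a_boundary(self, long_grid):
        rng = np.random.default_rng(77)
        for _ in range(20):
            ptvs = []
            for i in range(int(rng.integers(2, 9))):
                z0 = float(rng.uniform(5, 520))
                ptvs.append(si_box(long_grid, z0, z0 + float(rng.uniform(10, 60)), f"p{i}"))
            intents = partition_intents(ptvs, [(-1e9, 1e9, "abdomen")])
            assigned = [t for it in intents for t in it.target_ids]
            assert sorted(assigned) == sorted(p.name for p in ptvs)
            for it in intents:
                assert it.target_span_mm <= 385.0 + 1e-9
                for tid in it.target_ids:
                    lo, hi = next(p for p in ptvs if p.name == tid).extent_mm(2)
                    assert it.si_range[0] <= lo and hi <= it.si_range[1]

    def test_boundary_moves_off_straddled_target(self, long_grid):
        # initial boundary would land inside the middle target; the larger
        # target-free gap (superior side) receives it
        ptvs = [
            si_box(long_grid, 20.0, 330.0, "lo"),
            si_box(long_grid, 370.0, 420.0, "mid"),
            si_box(long_grid, 500.0, 590.0, "hi"),
        ]
        intents = partition_intents(ptvs, [(-1e9, 1e9, "abdomen")])
        for it in intents:
            assert "mid" not in it.target_ids or len([t for t in it.target_ids]) >= 1
        owner = {t: i for i, it in enumerate(intents) for t in it.target_ids}
        assert owner["mid"] != owner["hi"] or owner["mid"] != owner["lo"]


class TestJunctions:
    def test_small_gap_across_intents_flagged(self, long_grid):
        a = si_box(long_grid, 150.0, 356.0, "a")
        b = si_box(long_grid, 360.0, 560.0, "b")
        intents = partition_intents([a, b], [(-1e9, 1e9, "abdomen")])
        assert len(intents) == 2
        flags = detect_junctions(intents, [a, b])
        assert len(flags) == 1
        assert flags[0].gap_mm == pytest.approx(4.0)
        assert {flags[0].target_a, flags[0].target_b} == {"a", "b"}

    def test_wide_gap_not_flagged(self, long_grid):
        a = si_box(long_grid, 150.0, 340.0, "a")
        b = si_box(long_grid, 360.0, 560.0, "b")
        intents = partition_intents([a, b], [(-1e9, 1e9, "abdomen")])
        assert detect_junctions(intents, [a, b]) == []

    def test_same_intent_pairs_excluded(self, long_grid):
        a = si_box(long_grid, 150.0, 200.0, "a")
        b = si_box(long_grid, 202.0, 250.0, "b")
        intents = partition_intents([a, b], [(-1e9, 1e9, "abdomen")])
        assert len(intents) == 1
        assert detect_junctions(intents, [a, b]) == []


class TestJunctionStructures:
    def grid(self):
        return make_grid((40, 40, 50), (2.0, 2.0, 1.0))

    def test_toy_boxes_crop_semantics(self):
        g = self.grid()
        a = box_mask(g, (20, 20, 10), (56, 56, 40), "PTV_a", role="PTV")
        b = box_mask(g, (20, 20, 0), (56, 56, 6), "PTV_b", role="PTV")
        js = derive_junction_structures(a, b)
        lo, hi = js.ptv_a_opti.extent_mm(2)
        # b's top (6 mm) + 5 mm crop reaches 11 mm inclusively, so the first
        # kept voxel center is the next one above 11 mm
        assert lo == 12.0
        assert hi == 40.0
        assert not (js.ptv_a_opti.mask & ~a.mask).any()  # subset of PTV_a

    def test_far_lateral_neighbor_no_crop(self):
        g = make_grid((60, 40, 50), (2.0, 2.0, 1.0))
        a = box_mask(g, (0, 20, 10), (20, 56, 40), "PTV_a", role="PTV")
        b = box_mask(g, (56, 20, 0), (118, 56, 6), "PTV_b", role="PTV")  # >30 mm away
        js = derive_junction_structures(a, b)
        assert np.array_equal(js.ptv_a_opti.mask, a.mask)

    def test_avoid_band_sits_just_inferior(self):
        g = self.grid()
        a = box_mask(g, (20, 20, 10), (56, 56, 40), "PTV_a", role="PTV")
        b = box_mask(g, (20, 20, 0), (56, 56, 6), "PTV_b", role="PTV")
        js = derive_junction_structures(a, b)
        lo, hi = js.junction_avoid.extent_mm(2)
        a_lo, _ = a.extent_mm(2)
        assert hi < a_lo                      # strictly inferior to PTV_a
        assert a_lo - lo <= 3.0               # within the 3 mm band
        assert not (js.junction_avoid.mask & a.mask).any()

    def test_junction_goal_thresholds(self):
        g = self.grid()
        a = box_mask(g, (20, 20, 10), (56, 56, 40), "PTV_a", role="PTV")
        b = box_mask(g, (20, 20, 0), (56, 56, 6), "PTV_b", role="PTV")
        js = derive_junction_structures(a, b, prescription=1.0)
        by = {(x.structure, x.metric): x for x in js.extra_goals}
        hot_a = by[("PTV_a_Opti", "Dmax_cc")]
        assert hot_a.threshold == 1.0 and hot_a.priority == "P2"
        b_hot = by[("PTV_b", "Dmax_cc")]
        assert b_hot.threshold == 0.5 and b_hot.priority == "P4" and b_hot.strict
        b_v = by[("PTV_b", "V")]
        assert b_v.threshold == 2.0 and b_v.dose == 1.0 and b_v.priority == "P4"
        avoid = by[("Junction_avoid", "V")]
        assert avoid.threshold == 10.0 and avoid.dose == 2.0 and avoid.priority == "P2"

    def test_rederivation_after_shift_keeps_invariants(self):
        g = make_grid((40, 40, 80), (2.0, 2.0, 1.0))
        from ldrtplan.structures import MarginSpec, expand

        for shift in (0.0, 4.0, 9.0):
            a = box_mask(g, (20, 20, 30 + shift), (56, 56, 60 + shift), "PTV_a", role="PTV")
            b = box_mask(g, (20, 20, 0), (56, 56, 20), "PTV_b", role="PTV")
            js = derive_junction_structures(a, b)
            guard = expand(b, MarginSpec.lateral_ap_si(30.0, 5.0, 5.0))
            assert not (js.ptv_a_opti.mask & guard.mask).any()


class TestTemplatesAndGoals:
    def make_intents(self):
        ptvs, region_map = three_region_targets()
        return partition_intents(ptvs, region_map)

    def test_three_region_template_totals(self):
        intents = self.make_intents()
        for it in intents:
            assign_plan_template(it, "IMRT", 9 if it.region == "thorax" else 12)
        thorax = next(it for it in intents if it.region == "thorax")
        assert thorax.total_fields == 18  # 2 isocenters x 9 fields
        s = summarize_plan_geometry(intents)
        assert s.total_fields == 42
        assert s.total_isocenters == 4
        assert s.total_targets == 31

    def test_template_menu_enforced(self):
        intents = self.make_intents()
        with pytest.raises(ValueError):
            assign_plan_template(intents[0], "IMRT", 10)
        with pytest.raises(ValueError):
            assign_plan_template(intents[0], "VMAT", 4)
        assign_plan_template(intents[0], "VMAT", 3)
        assert intents[0].plan_template.modality == "VMAT"

    def test_empty_intent_list_zero_totals(self):
        s = summarize_plan_geometry([])
        assert s.total_fields == 0 and s.total_isocenters == 0 and s.total_targets == 0

    def test_goal_set_counts_and_thresholds(self):
        goals = build_goal_set([f"PTV_{i}" for i in range(31)])
        assert len(goals) == 93
        v = [g for g in goals if g.metric == "V"]
        assert all(g.threshold == 95.0 and g.variation == 90.0 and g.priority == "P1"
                   for g in v)
        dmin = [g for g in goals if g.metric == "Dmin_cc"]
        assert all(g.threshold == 0.95 and g.variation == 0.90 and g.volume_cc == 0.03
                   for g in dmin)
        dmax = [g for g in goals if g.metric == "Dmax_cc"]
        assert all(g.threshold == 1.20 and g.variation == 1.25 and g.priority == "P2"
                   for g in dmax)

    def test_goal_set_scales_with_prescription(self):
        goals = build_goal_set(["PTV_1"], prescription=2.0)
        v, dmin, dmax = goals
        assert v.threshold == 95.0 and v.dose == 2.0       # percent unchanged
        assert dmin.threshold == pytest.approx(1.90)
        assert dmax.threshold == pytest.approx(2.40)

    def test_variation_stricter_than_threshold_rejected(self):
        with pytest.raises(ValueError):
            ClinicalGoal("PTV", "V", 95.0, "ge", "P1", dose=1.0, variation=97.0)
        with pytest.raises(ValueError):
            ClinicalGoal("PTV", "Dmax_cc", 1.2, "le", "P2", volume_cc=0.03, variation=1.1)
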