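"""DVH queries, goal grading, conformality metrics and cohort summaries."""

import numpy as np
import pytest

from ldrtplan.core import StructureMask
from ldrtplan.evaluation import (
    PlanEvaluation,
    compute_dvh,
    conformality_metrics,
    dose_at_volume,
    evaluate_plan,
    grade_goals,
    summarize_cohort,
    volume_at_dose,
)
from ldrtplan.plangeom import ClinicalGoal, build_goal_set

from conftest import box_mask, dose_from_array, make_grid, uniform_dose


class TestDVH:
    def test_uniform_dose_queries(self, grid20):
        m = box_mask(grid20, (4, 4, 4), (30, 30, 30))
        dvh = compute_dvh(uniform_dose(grid20, 1.0), m)
        assert volume_at_dose(dvh, 1.0) == 100.0
        assert volume_at_dose(dvh, 1.0 + 1e-6) == 0.0
        for v in (0.01, 0.03, dvh.total_volume_cc / 2):
            assert dose_at_volume(dvh, v, "cold") == 1.0
            assert dose_at_volume(dvh, v, "hot") == 1.0

    def test_two_level_dose(self, grid20):
        m = box_mask(grid20, (0, 0, 0), (38, 38, 38))
        vals = np.full(grid20.shape, 1.0)
        half = grid20.shape[2] // 2
        vals[:, :, :half] = 0.5
        dvh = compute_dvh(dose_from_array(grid20, vals), m)
        assert volume_at_dose(dvh, 0.75) == pytest.approx(50.0)

    def test_plateau_boundary_pins(self):
        """A 1.00 cc structure with the coldest 0.02 cc at 0.5 Gy: the
        0.03 cc cold query lands in the 1.0 Gy plateau (step semantics)."""
        grid = make_grid((100, 1, 1), (10.0, 1.0, 1.0))  # 0.01 cc voxels
        m = StructureMask("s", np.ones(grid.shape, bool), grid)
        vals = np.ones(grid.shape)
        vals[:2] = 0.5  # 0.02 cc at 0.5 Gy
        dvh = compute_dvh(dose_from_array(grid, vals), m)
        assert dvh.voxel_volume_cc == pytest.approx(0.01)
        assert dose_at_volume(dvh, 0.03, "cold") == 1.0
        # exact plateau boundary resolves to the colder value
        assert dose_at_volume(dvh, 0.02, "cold") == 0.5
        # hottest one-voxel query returns that voxel's dose
        vals2 = np.ones(grid.shape)
        vals2[50] = 1.3
        dvh2 = compute_dvh(dose_from_array(grid, vals2), m)
        assert dose_at_volume(dvh2, 0.01, "hot") == 1.3

    def test_volume_bounds_enforced(self, grid20):
        m = box_mask(grid20, (4, 4, 4), (10, 10, 10))
        dvh = compute_dvh(uniform_dose(grid20, 1.0), m)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 0.0, "cold")
        with pytest.raises(ValueError):
            dose_at_volume(dvh, dvh.total_volume_cc * 2, "cold")

    def test_queries_match_brute_force_oracle(self):
        rng = np.random.default_rng(404)
        for _ in range(40):
            grid = make_grid(tuple(rng.integers(6, 15, 3)), tuple(rng.uniform(1, 4, 3)))
            mask = rng.random(grid.shape) < 0.4
            if not mask.any():
                mask[0, 0, 0] = True
            m = StructureMask("m", mask, grid)
            dose = dose_from_array(grid, rng.random(grid.shape) * 2)
            dvh = compute_dvh(dose, m)
            vox = grid.voxel_volume_cc
            vals = np.sort(dose.dose.values[mask])
            # V_D oracle: count voxels >= D
            for dlev in rng.uniform(0, 2, 3):
                assert volume_at_dose(dvh, dlev) == pytest.approx(
                    100.0 * (vals >= dlev - 1e-12).sum() / vals.size
                )
            # D at volume oracle: walk the sorted list
            for v in rng.uniform(vox / 2, vals.size * vox, 3):
                k = int(np.ceil(v / vox - 1e-12)) - 1
                assert dose_at_volume(dvh, v, "cold") == vals[k]
                assert dose_at_volume(dvh, v, "hot") == vals[::-1][k]

    def test_min_mean_max_ordering(self, grid20):
        rng = np.random.default_rng(5)
        m = box_mask(grid20, (4, 4, 4), (30, 30, 30))
        dose = dose_from_array(grid20, rng.random(grid20.shape))
        dvh = compute_dvh(dose, m)
        dmin = dose_at_volume(dvh, 0.03, "cold")
        dmax = dose_at_volume(dvh, 0.03, "hot")
        assert dmin <= dvh.mean_dose <= dmax


class TestGrading:
    def structures(self, grid):
        return {"PTV": box_mask(grid, (4, 4, 4), (30, 30, 30), "PTV")}

    def test_all_goals_pass_at_prescription(self, grid20):
        structs = self.structures(grid20)
        results = grade_goals(uniform_dose(grid20, 1.0), structs, build_goal_set(["PTV"]))
        assert [r.grade for r in results] == ["pass", "pass", "pass"]

    def test_coverage_in_variation_band(self, grid20):
        structs = self.structures(grid20)
        vals = np.ones(grid20.shape)
        mask = structs["PTV"].mask
        idx = np.argwhere(mask)
        n_cold = int(round(0.08 * len(idx)))  # 92% coverage
        for i, j, k in idx[:n_cold]:
            vals[i, j, k] = 0.97
        results = grade_goals(dose_from_array(grid20, vals), structs,
                              build_goal_set(["PTV"]))
        v_goal = next(r for r in results if r.goal.metric == "V")
        assert v_goal.achieved_value == pytest.approx(92.0, abs=0.5)
        assert v_goal.grade == "variation"

    def test_hotspot_beyond_variation_fails(self, grid20):
        structs = self.structures(grid20)
        vals = np.ones(grid20.shape)
        vals[8:10, 8:10, 8:10] = 1.30  # 0.064 cc hotspot > 0.03 cc
        results = grade_goals(dose_from_array(grid20, vals), structs,
                              build_goal_set(["PTV"]))
        hot = next(r for r in results if r.goal.metric == "Dmax_cc")
        assert hot.achieved_value == pytest.approx(1.30)
        assert hot.grade == "fail"

    def test_missing_structure_named(self, grid20):
        with pytest.raises(KeyError, match="Ghost"):
            grade_goals(uniform_dose(grid20, 1.0), self.structures(grid20),
                        build_goal_set(["Ghost"]))

    def test_strict_goal_boundary(self, grid20):
        structs = self.structures(grid20)
        goal = ClinicalGoal("PTV", "Dmax_cc", 0.5, "le", "P4", volume_cc=0.03, strict=True)
        res = grade_goals(uniform_dose(grid20, 0.5), structs, [goal])
        assert res[0].grade == "fail"  # equality does not satisfy '<'


class TestConformality:
    def test_perfectly_conformal_limit(self, grid20):
        ptv = box_mask(grid20, (10, 10, 10), (26, 26, 26), "PTV")
        ext = box_mask(grid20, (0, 0, 0), (38, 38, 38), "ext", role="external")
        vals = np.where(ptv.mask, 1.0, 0.0)
        m = conformality_metrics(dose_from_array(grid20, vals), ptv, ext)
        assert m.ci == pytest.approx(1.0)
        assert m.r50 == pytest.approx(1.0)
        assert m.d2cm_pct == 0.0

    def test_sphere_isodose_volume_ratio(self):
        """50% isodose at twice the target radius gives R50 ~ 8."""
        grid = make_grid((60, 60, 60), (1.5, 1.5, 1.5))
        x, y, z = grid.meshgrid()
        c = 44.25
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        ptv = StructureMask("PTV", r <= 10.0, grid, role="PTV")
        ext = box_mask(grid, (0, 0, 0), (88.5, 88.5, 88.5), "ext", role="external")
        vals = np.where(r <= 10.0, 1.0, np.where(r <= 20.0, 0.5, 0.0))
        m = conformality_metrics(dose_from_array(grid, vals), ptv, ext)
        assert m.r50 == pytest.approx(8.0, rel=0.1)

    def test_matches_brute_force_on_random_grids(self):
        from ldrtplan.structures import distance_map

        rng = np.random.default_rng(99)
        for _ in range(10):
            grid = make_grid((12, 12, 12), tuple(rng.uniform(2, 4, 3)))
            ptv_mask = np.zeros(grid.shape, bool)
            ptv_mask[4:7, 4:7, 4:7] = True
            ptv = StructureMask("PTV", ptv_mask, grid, role="PTV")
            ext = StructureMask("ext", np.ones(grid.shape, bool), grid, role="external")
            vals = rng.random(grid.shape) * 1.5
            d = dose_from_array(grid, vals)
            m = conformality_metrics(d, ptv, ext)
            vox = grid.voxel_volume_cc
            assert m.r50 == pytest.approx((vals >= 0.5).sum() * vox / ptv.volume_cc)
            assert m.ci == pytest.approx((vals >= 1.0).sum() * vox / ptv.volume_cc)
            far = distance_map(ptv).values >= 20.0
            assert m.d2cm_pct == pytest.approx(100 * vals[far].max())

    def test_degenerate_body_rejected(self, grid20):
        ptv = box_mask(grid20, (0, 0, 0), (38, 38, 38), "PTV")
        ext = ptv.with_name("ext", role="external")
        with pytest.raises(ValueError):
            conformality_metrics(uniform_dose(grid20, 1.0), ptv, ext)


class TestCohort:
    def eval_with(self, pct):
        ev = PlanEvaluation(goal_results=[])
        ev.pct_goals_met = {"V_1Gy >= 95% (P1)": pct}
        return ev

    def test_single_plan_all_pass(self):
        grid = make_grid((30, 30, 30))
        ptv = box_mask(grid, (8, 8, 8), (20, 20, 20), "PTV")
        ext = box_mask(grid, (0, 0, 0), (58, 58, 58), "ext", role="external")
        ev = evaluate_plan(uniform_dose(grid, 1.0), {"PTV": ptv},
                           build_goal_set(["PTV"]), ptv, ext)
        df = summarize_cohort([ev], ["initial"])
        assert df.loc["V_1Gy >= 95% (P1)", ("mean", "initial")] == 100.0

    def test_mean_and_sample_sd(self):
        df = summarize_cohort([self.eval_with(80.0), self.eval_with(100.0)],
                              ["adapted", "adapted"])
        assert df.loc["V_1Gy >= 95% (P1)", ("mean", "adapted")] == pytest.approx(90.0)
        assert df.loc["V_1Gy >= 95% (P1)", ("std", "adapted")] == pytest.approx(14.142, abs=0.01)

    def test_absent_goal_class_is_nan_not_zero(self):
        ev2 = PlanEvaluation(goal_results=[])
        ev2.pct_goals_met = {"D0.03cc <= 1.2 Gy (P2)": 50.0}
        df = summarize_cohort([self.eval_with(80.0), ev2], ["a", "b"])
        assert np.isnan(df.loc["V_1Gy >= 95% (P1)", ("mean", "b")])
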