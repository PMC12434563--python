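"""Pipeline orchestration and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vesselprox.cohort import (
    PipelineConfig,
    PipelineError,
    manual_vs_auto,
    run_case,
    run_cohort,
    stage_anova,
)
from vesselprox.phantoms import make_cohort, rasterize
from vesselprox.volume_io import LabelVolume, write_label_volume


class TestRunCase:
    def test_report_matches_phantom_truth(self, tube_sphere_phantom):
        _, tumor, vessel, truth = tube_sphere_phantom
        rep = run_case(tumor, vessel, case_id="c1", stage="T2")
        assert rep.case_id == "c1" and rep.stage == "T2"
        assert rep.dtica_mm == pytest.approx(truth["dtica_mm"], abs=np.sqrt(3))
        assert rep.dtica_mm <= min(rep.per_side_min_mm) + 1e-12
        assert all(v >= 0 for v in (rep.dtica_mm, rep.mdp_arc_mm, rep.volume_mm3,
                                    rep.surface_area_mm2, rep.td_mm))

    def test_empty_tumor_error_names_stage(self, tube_sphere_phantom):
        _, tumor, vessel, _ = tube_sphere_phantom
        empty = LabelVolume(np.zeros_like(tumor.voxels), tumor.spacing)
        with pytest.raises(PipelineError, match="extract_tumor_label"):
            run_case(empty, vessel, case_id="bad")

    def test_rerun_identical(self, tube_sphere_phantom):
        _, tumor, vessel, _ = tube_sphere_phantom
        r1 = run_case(tumor, vessel)
        r2 = run_case(tumor, vessel)
        assert r1 == r2

    def test_from_files(self, tmp_path, tube_sphere_phantom):
        _, tumor, vessel, truth = tube_sphere_phantom
        tp, vp = tmp_path / "t.nii.gz", tmp_path / "v.nii.gz"
        write_label_volume(tumor, tp)
        write_label_volume(vessel, vp)
        rep = run_case(str(tp), str(vp))
        assert rep.dtica_mm == pytest.approx(truth["dtica_mm"], abs=np.sqrt(3))


class TestRunCohort:
    @pytest.fixture(scope="class")
    def small_manifest(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("cohort")
        rows = []
        for case_id, stage, spec in make_cohort(n_per_stage=2, seed=9,
                                                shape=(80, 96, 96)):
            tumor, vessel, _ = rasterize(spec)
            tp = out / f"{case_id}_t.nii.gz"
            vp = out / f"{case_id}_v.nii.gz"
            write_label_volume(tumor, tp)
            write_label_volume(vessel, vp)
            rows.append({"case_id": case_id, "stage": stage,
                         "tumor_path": str(tp), "vessel_path": str(vp)})
        path = out / "manifest.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_reports_one_row_per_case(self, small_manifest):
        table = run_cohort(small_manifest)
        assert len(table) == 8
        assert {"case_id", "stage", "dtica_mm", "mdp_arc_mm", "volume_mm3"} <= set(table.columns)

    def test_csv_roundtrip_lossless(self, small_manifest, tmp_path):
        table = run_cohort(small_manifest)
        p = tmp_path / "reports.csv"
        table.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(
            back[["dtica_mm", "mdp_arc_mm"]], table[["dtica_mm", "mdp_arc_mm"]]
        )

    def test_byte_identical_reruns(self, small_manifest, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        run_cohort(small_manifest).to_csv(p1, index=False)
        run_cohort(small_manifest).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            run_cohort(pd.DataFrame({"case_id": ["a"]}))


class TestStageAnova:
    @staticmethod
    def frame(groups: dict[str, list[float]], measure="dtica_mm"):
        rows = [{"stage": s, measure: v} for s, vals in groups.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_groups_f_zero_p_one(self):
        table = self.frame({"T1": [1, 2, 3], "T2": [1, 2, 3]})
        cs = stage_anova(table, measures=("dtica_mm",))
        assert cs.anova_f["dtica_mm"] == pytest.approx(0.0, abs=1e-12)
        assert cs.anova_p["dtica_mm"] == pytest.approx(1.0)

    def test_two_groups_anova_equals_squared_t(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        table = self.frame({"T1": a, "T2": b})
        cs = stage_anova(table, measures=("dtica_mm",))
        t = stats.ttest_ind(a, b, equal_var=True)
        assert cs.anova_f["dtica_mm"] == pytest.approx(t.statistic**2, rel=1e-12)
        assert cs.anova_p["dtica_mm"] == pytest.approx(t.pvalue, rel=1e-12)
        assert cs.pairwise_p["dtica_mm"].loc["T1", "T2"] == pytest.approx(t.pvalue, rel=1e-12)

    def test_textbook_three_point_groups(self):
        # closed-form one-way ANOVA on tiny hand-checkable groups:
        # groups {0,1,2}, {2,3,4}, {4,5,6}: grand mean 3, SSB=3*8=24, SSW=6
        # F = (24/2)/(6/6) = 12
        table = self.frame({"T1": [0, 1, 2], "T2": [2, 3, 4], "T3": [4, 5, 6]})
        cs = stage_anova(table, measures=("dtica_mm",))
        assert cs.anova_f["dtica_mm"] == pytest.approx(12.0, rel=1e-12)

    def test_pairwise_matrix_symmetric(self):
        rng = np.random.default_rng(0)
        table = self.frame({f"T{i}": list(rng.normal(i, 1, 6)) for i in range(1, 5)})
        cs = stage_anova(table, measures=("dtica_mm",))
        m = cs.pairwise_p["dtica_mm"]
        for i in m.index:
            for j in m.columns:
                if i != j:
                    assert m.loc[i, j] == m.loc[j, i]
                    assert 0 <= m.loc[i, j] <= 1

    def test_holm_correction_never_decreases_p(self):
        rng = np.random.default_rng(1)
        table = self.frame({f"T{i}": list(rng.normal(i * 0.5, 1, 8)) for i in range(1, 5)})
        raw = stage_anova(table, measures=("dtica_mm",)).pairwise_p["dtica_mm"]
        adj = stage_anova(table, measures=("dtica_mm",), holm=True).pairwise_p["dtica_mm"]
        raw_v, adj_v = raw.stack(), adj.stack()
        assert (adj_v >= raw_v - 1e-15).all()
        assert (adj_v <= 1.0).all()

    def test_pearson_r_and_r2(self):
        rng = np.random.default_rng(2)
        n = 40
        vol = rng.uniform(1000, 30000, n)
        dtica = 10 - vol / 5000 + rng.normal(0, 1, n)
        table = pd.DataFrame({
            "stage": ["T1", "T2"] * (n // 2), "dtica_mm": dtica, "volume_mm3": vol,
        })
        cs = stage_anova(table, measures=("dtica_mm", "volume_mm3"))
        r_expected = stats.pearsonr(vol, dtica).statistic
        assert cs.pearson_r["volume_mm3"] == pytest.approx(r_expected, rel=1e-12)
        assert cs.pearson_r2["volume_mm3"] == pytest.approx(r_expected**2, rel=1e-12)
        assert -1 <= cs.pearson_r["volume_mm3"] <= 1

    def test_pearson_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        n = 30
        vol = rng.uniform(1, 10, n)
        dtica = rng.uniform(1, 10, n)
        table = pd.DataFrame({"stage": ["T1", "T2"] * 15, "dtica_mm": dtica, "volume_mm3": vol})
        r0 = stage_anova(table, measures=("dtica_mm", "volume_mm3")).pearson_r["volume_mm3"]
        table2 = table.assign(volume_mm3=3.5 * table.volume_mm3 + 100.0)
        r1 = stage_anova(table2, measures=("dtica_mm", "volume_mm3")).pearson_r["volume_mm3"]
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="two stage groups"):
            stage_anova(self.frame({"T1": [1, 2, 3]}), measures=("dtica_mm",))
        with pytest.raises(ValueError, match="two observations"):
            stage_anova(self.frame({"T1": [1, 2], "T2": [3]}), measures=("dtica_mm",))
        with pytest.raises(ValueError, match="zero variance"):
            stage_anova(self.frame({"T1": [2, 2], "T2": [2, 2]}), measures=("dtica_mm",))


class TestManualVsAuto:
    def test_identical_lists_zero_difference(self):
        diff, p = manual_vs_auto([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert diff == 0.0
        assert p == 1.0

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(4)
        truth = rng.uniform(2, 12, 30)
        auto = truth + 0.7 + rng.normal(0, 0.05, 30)
        manual = truth
        diff, p = manual_vs_auto(auto, manual)
        assert diff == pytest.approx(0.7, abs=0.05)
        assert p < 0.001

    def test_null_distribution_of_p_is_uniformish(self):
        """Equal-noise auto and manual readings: p should not pile up low."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            truth = rng.uniform(2, 12, 60)
            auto = truth + rng.normal(0, 0.3, 60)
            manual = truth + rng.normal(0, 0.3, 60)
            pvals.append(manual_vs_auto(auto, manual)[1])
        assert np.mean(np.asarray(pvals) < 0.05) < 0.12
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            manual_vs_auto([1.0, 2.0], [1.0])
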