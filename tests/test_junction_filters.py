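"""Junction gaps, closure error, superposition RMSD, filter cascades."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symbond.building_blocks import AttachmentFrame
from symbond.geometry import rotation_about_axis
from symbond.junction_filters import (
    ClosureError,
    DesignMetrics,
    FilterSpec,
    MissingMetricError,
    apply_interface_filters,
    apply_prediction_filters,
    closure_error,
    filter_table,
    gap_transform,
    kabsch_rmsd,
    read_metrics_tsv,
)


def random_frame(rng):
    R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 360))
    return AttachmentFrame(origin=rng.uniform(-30, 30, 3), basis=R)


class TestGapTransform:
    def test_identical_frames_give_identity(self):
        f = AttachmentFrame.identity()
        T = gap_transform(f, f)
        assert np.allclose(T.R, np.eye(3)) and np.allclose(T.t, 0)

    def test_pure_translation(self):
        a = AttachmentFrame.identity()
        b = AttachmentFrame(origin=np.array([5.0, 0, 0]), basis=np.eye(3))
        T = gap_transform(a, b)
        assert np.allclose(T.R, np.eye(3)) and np.allclose(T.t, [5, 0, 0])

    def test_random_frames_self_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_frame(rng), random_frame(rng)
            T = gap_transform(a, b)
            moved = a.transformed(T)
            assert np.allclose(moved.origin, b.origin, atol=1e-12)
            assert np.allclose(moved.basis, b.basis, atol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ValueError):
            AttachmentFrame(origin=np.zeros(3), basis=np.eye(3) * 1.1)


class TestClosureError:
    def test_identical_frames_zero(self):
        f = AttachmentFrame.identity()
        e = closure_error(f, f)
        assert e.d_trans == 0 and e.d_rot == 0 and e.combined == 0

    def test_pure_offset_combined_score(self):
        a = AttachmentFrame.identity()
        b = AttachmentFrame(origin=np.array([1.0, 0, 0]), basis=np.eye(3))
        e = closure_error(a, b, lever_arm=10.0, scale=10.0)
        assert e.combined == pytest.approx(0.1)
        assert e.d_rot == 0

    def test_pure_twist_combined_score(self):
        a = AttachmentFrame.identity()
        b = AttachmentFrame(origin=np.zeros(3), basis=rotation_about_axis((0, 0, 1), np.degrees(0.1)))
        e = closure_error(a, b, lever_arm=10.0, scale=10.0)
        assert e.combined == pytest.approx(0.1)
        assert e.d_trans == 0

    def test_rotation_error_invariant_under_global_motion(self):
        rng = np.random.default_rng(1)
        a, b = random_frame(rng), random_frame(rng)
        e0 = closure_error(a, b)
        from symbond.geometry import RigidTransform

        T = RigidTransform(rotation_about_axis((1, 1, 0), 77.0), np.array([3.0, -2, 9]))
        e1 = closure_error(a.transformed(T), b.transformed(T))
        assert e1.d_rot == pytest.approx(e0.d_rot, abs=1e-9)
        assert e1.d_trans == pytest.approx(e0.d_trans, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ClosureError(d_trans=-1.0, d_rot=0.0, combined=0.0)


class TestKabschRmsd:
    def test_self_is_zero(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3))
        assert kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_zero(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(12, 3))
        B = A @ rotation_about_axis((1, 2, 3), 50.0).T + np.array([4.0, 5, 6])
        assert kabsch_rmsd(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        A = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        B = np.array([[-2.0, 0, 0], [2.0, 0, 0]])
        assert kabsch_rmsd(A, B) == pytest.approx(1.0)

    def test_matches_brute_force_rotation_search(self):
        """Independent oracle: coarse random rotation grid followed by
        derivative-free local minimization over the rotation vector —
        no SVD anywhere in the reference path."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 3)) * 5
        B = rng.normal(size=(5, 3)) * 5
        Ac, Bc = A - A.mean(0), B - B.mean(0)

        def cost(rotvec):
            M = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((Bc @ M.T - Ac) ** 2, axis=1)))

        grid = Rotation.random(2000, random_state=7).as_rotvec()
        best_start = min(grid, key=cost)
        best = minimize(cost, best_start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
        assert kabsch_rmsd(A, B) <= best + 1e-9
        assert kabsch_rmsd(A, B) == pytest.approx(best, abs=1e-3)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


GOOD_PRED = dict(plddt=95.0, ptm=0.85, ca_rmsd=1.2)
GOOD_IFACE = dict(met_count=4, sc=0.65, ddg=-25.0, sasa=1500.0, clash=1, unsat_hb=2)


class TestPredictionFilters:
    def test_passing_design(self):
        assert apply_prediction_filters(DesignMetrics(**GOOD_PRED), rmsd_cut=1.5).passed

    def test_boundary_plddt_fails_strict_inequality(self):
        r = apply_prediction_filters(DesignMetrics(**{**GOOD_PRED, "plddt": 90.0}))
        assert not r.passed and any("plddt" in s for s in r.reasons)

    def test_rmsd_cut_two_angstrom(self):
        assert apply_prediction_filters(DesignMetrics(**{**GOOD_PRED, "ca_rmsd": 1.8}), rmsd_cut=2.0).passed
        assert not apply_prediction_filters(DesignMetrics(**{**GOOD_PRED, "ca_rmsd": 1.8}), rmsd_cut=1.5).passed

    def test_missing_metric_policies(self):
        m = DesignMetrics(plddt=95.0, ptm=0.85)
        r = apply_prediction_filters(m)
        assert not r.passed and any("missing" in s for s in r.reasons)
        with pytest.raises(MissingMetricError):
            apply_prediction_filters(m, strict=True)


class TestInterfaceFilters:
    def test_passing_design(self):
        assert apply_interface_filters(DesignMetrics(**GOOD_IFACE)).passed

    @pytest.mark.parametrize(
        "field,value",
        [("ddg", -15.0), ("met_count", 6), ("sc", 0.6), ("sasa", 1600.0), ("clash", 3), ("unsat_hb", 3), ("ddg", -20.0)],
    )
    def test_failing_boundaries(self, field, value):
        r = apply_interface_filters(DesignMetrics(**{**GOOD_IFACE, field: value}))
        assert not r.passed and any(field in s for s in r.reasons)

    @pytest.mark.parametrize("field,value", [("met_count", 5), ("clash", 2), ("unsat_hb", 2)])
    def test_passing_boundaries_non_strict_clauses(self, field, value):
        assert apply_interface_filters(DesignMetrics(**{**GOOD_IFACE, field: value})).passed

    def test_sap_clause_only_when_present(self):
        assert apply_interface_filters(DesignMetrics(**GOOD_IFACE)).passed
        assert not apply_interface_filters(DesignMetrics(**GOOD_IFACE, sap=30.0)).passed
        assert apply_interface_filters(DesignMetrics(**GOOD_IFACE, sap=29.0)).passed


@given(
    st.sampled_from(list(GOOD_IFACE)),
    st.floats(min_value=0.1, max_value=50.0, allow_nan=False),
)
@settings(deadline=None, max_examples=50)
def test_filters_are_monotone(field, delta):
    """Worsening any single metric never converts fail into pass."""
    base = DesignMetrics(**GOOD_IFACE)
    worse_dir = {"met_count": +1, "sc": -1, "ddg": +1, "sasa": +1, "clash": +1, "unsat_hb": +1}
    worse = DesignMetrics(**{**GOOD_IFACE, field: GOOD_IFACE[field] + worse_dir[field] * delta})
    if not apply_interface_filters(base).passed:
        return
    better_passed = apply_interface_filters(base).passed
    worse_passed = apply_interface_filters(worse).passed
    assert better_passed or not worse_passed


class TestFilterTable:
    def test_empty_table(self):
        survivors, audit = filter_table([], FilterSpec.interface())
        assert survivors == [] and audit == []

    def test_no_clauses_all_survive(self):
        rows = [DesignMetrics(plddt=50.0), DesignMetrics()]
        survivors, _ = filter_table(rows, FilterSpec(clauses=()))
        assert survivors == rows

    def test_hand_applied_thresholds(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(
            "design_id\tplddt\tptm\tca_rmsd\n"
            "d1\t95\t0.85\t1.2\n"
            "d2\t89\t0.90\t1.0\n"
            "d3\t95\t0.70\t1.0\n"
        )
        rows = read_metrics_tsv(tsv)
        survivors, audit = filter_table(rows, FilterSpec.prediction(rmsd_cut=1.5))
        assert [r.design_id for r in survivors] == ["d1"]
        assert "FAIL" in audit[1] and "plddt" in audit[1]

    def test_malformed_value_reports_line(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text("plddt\tptm\tca_rmsd\n95\tnot_a_number\t1.2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_metrics_tsv(tsv)
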