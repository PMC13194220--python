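"""Final alignment: the penalty objective, its weights, the clinical pose
bounds and the constrained refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plateplan import (
    ObjectiveTerms,
    ObjectiveWeights,
    RigidPose,
    TriMesh,
    build_bounds,
    compute_objective_terms,
    objective_value,
)
from plateplan.final_alignment import BoundsError, _ObjectiveContext
from plateplan.landmarks import watershed_interp

PAPER_WEIGHTS = ObjectiveWeights()  # a=105, b=100, c=4, d=5, e=60


def _terms(**kw):
    base = dict(d_plate=0.0, d_top=0.0, d_bottom=0.0, M_penalty=0, theta_penalty=0.0, y_dev=0.0)
    base.update(kw)
    return ObjectiveTerms(**base)


class TestObjectiveValue:
    def test_all_zero_terms(self):
        assert objective_value(_terms(), PAPER_WEIGHTS) == 0.0

    def test_unweighted_plate_distance_term(self):
        assert objective_value(_terms(d_plate=1.0), PAPER_WEIGHTS) == 1.0

    def test_top_corner_weight(self):
        # the distal corner distance carries weight a = 105
        assert objective_value(_terms(d_top=2.0), PAPER_WEIGHTS) == 210.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(0, 1e3, allow_nan=False, allow_infinity=False),
            min_size=5,
            max_size=5,
        ),
        m=st.integers(0, 500),
        w=st.lists(st.floats(0, 500), min_size=5, max_size=5),
    )
    def test_linear_combination_matches_hand_computation(self, vals, m, w):
        terms = ObjectiveTerms(vals[0], vals[1], vals[2], m, vals[3], vals[4])
        weights = ObjectiveWeights(*w)
        expect = (
            vals[0] + w[0] * vals[1] + w[1] * vals[2] + w[2] * m + w[3] * vals[3] + w[4] * vals[4]
        )
        assert abs(objective_value(terms, weights) - expect) < 1e-9

    def test_negative_weight_rejected(self):
        with pytest.raises(Exception):
            ObjectiveWeights(a=-1.0)


class TestObjectiveTerms:
    def test_plate_against_itself_has_zero_distance(self, standard_case):
        plate = standard_case["plate_std"]
        lm = standard_case["plate_lm"]
        t = compute_objective_terms(RigidPose.identity(), plate, lm, plate)
        assert t.d_plate == 0.0
        assert t.M_penalty == 0

    def test_bottom_distance_matches_exhaustive_minimum(self, standard_case, rng):
        # flat slab of bone vertices; oracle is the explicit O(n) minimum
        ys, zs = np.meshgrid(np.arange(-20.0, 21.0), np.arange(-30.0, 31.0))
        slab_v = np.column_stack(
            [np.zeros(ys.size), ys.ravel(), zs.ravel()]
        )
        slab = TriMesh(slab_v, np.asarray([[0, 1, 61], [1, 62, 61], [2, 3, 63], [3, 64, 63]]))
        plate = standard_case["plate_std"]
        lm = standard_case["plate_lm"]
        pose = RigidPose(np.zeros(3), np.array([5.0, 0.3, 0.7]))
        t = compute_objective_terms(pose, plate, lm, slab)
        bottom = pose.apply(lm.bottom)[0]
        oracle = np.sqrt(((slab_v - bottom) ** 2).sum(axis=1)).min()
        assert abs(t.d_bottom - oracle) < 1e-9

    def test_full_containment_counts_every_vertex(self, standard_case):
        import trimesh as tm

        plate = standard_case["plate_std"]
        lm = standard_case["plate_lm"]
        box = tm.creation.box(extents=(200, 200, 200))
        bone = TriMesh(np.asarray(box.vertices), np.asarray(box.faces))
        t = compute_objective_terms(RigidPose.identity(), plate, lm, bone)
        assert t.M_penalty == plate.n_vertices

    def test_invariant_under_simultaneous_rigid_motion(self, standard_case, initial_fixture):
        from scipy.spatial.transform import Rotation

        sc = standard_case
        t0 = compute_objective_terms(
            initial_fixture.pose, sc["plate_std"], sc["plate_lm"], sc["bone_std"]
        )
        r = Rotation.from_euler("xyz", [25, -40, 60], degrees=True).as_matrix()
        shift = np.array([12.0, -7.0, 30.0])
        bone_moved = sc["bone_std"].transformed(r, shift)
        motion = RigidPose.from_matrix(r, shift)
        pose_moved = motion.compose(initial_fixture.pose)
        t1 = compute_objective_terms(
            pose_moved, sc["plate_std"], sc["plate_lm"], bone_moved
        )
        assert abs(t0.d_plate - t1.d_plate) < 1e-6
        assert abs(t0.d_top - t1.d_top) < 1e-6
        assert abs(t0.d_bottom - t1.d_bottom) < 1e-6
        assert t0.M_penalty == t1.M_penalty
        assert abs(t0.theta_penalty - t1.theta_penalty) < 1e-6
        assert abs(t0.y_dev - t1.y_dev) < 1e-6


class TestBounds:
    def test_x_half_width_is_quarter_radius(self, standard_case, initial_fixture):
        sc = standard_case
        b = build_bounds(initial_fixture.pose, sc["bone_lm"], sc["plate_lm"], sc["bone_std"])
        half = (b.x_range[1] - b.x_range[0]) / 2.0
        assert np.isclose(half, sc["bone_lm"].radius_width / 4.0)

    def test_z_lower_bound_is_1p5_plate_lengths_below_top(
        self, standard_case, initial_fixture
    ):
        sc = standard_case
        b = build_bounds(initial_fixture.pose, sc["bone_lm"], sc["plate_lm"], sc["bone_std"])
        expect = sc["bone_std"].vertices[:, 2].max() - 1.5 * sc["plate_lm"].plate_length
        assert np.isclose(b.z_range[0], expect)
        assert np.isclose(b.z_range[1], sc["bone_lm"].watershed[:, 2].max())

    def test_rotation_limits_are_pm_30_degrees(self, standard_case, initial_fixture):
        sc = standard_case
        b = build_bounds(initial_fixture.pose, sc["bone_lm"], sc["plate_lm"], sc["bone_std"])
        lim = np.asarray(b.rot_limits)
        assert np.allclose(lim[:, 1] - lim[:, 0], 60.0)

    def test_initial_pose_strictly_interior_in_rotation_and_xy(
        self, standard_case, initial_fixture
    ):
        sc = standard_case
        b = build_bounds(initial_fixture.pose, sc["bone_lm"], sc["plate_lm"], sc["bone_std"])
        assert b.contains(initial_fixture.pose)

    def test_inverted_interval_rejected(self, standard_case, initial_fixture):
        from dataclasses import replace

        sc = standard_case
        tiny_plate_lm = replace(sc["plate_lm"], plate_length=1.0)
        with pytest.raises(BoundsError):
            build_bounds(initial_fixture.pose, sc["bone_lm"], tiny_plate_lm, sc["bone_std"])


class TestOptimizePose:
    def test_monotone_improvement(self, standard_case, initial_fixture, optimized_fixture):
        sc = standard_case
        t0 = compute_objective_terms(
            initial_fixture.pose, sc["plate_std"], sc["plate_lm"], sc["bone_std"]
        )
        f0 = objective_value(t0, PAPER_WEIGHTS)
        assert optimized_fixture.objective_value <= f0 + 1e-9

    def test_pose_within_bounds(self, standard_case, initial_fixture, optimized_fixture):
        sc = standard_case
        b = build_bounds(initial_fixture.pose, sc["bone_lm"], sc["plate_lm"], sc["bone_std"])
        assert b.contains(optimized_fixture.pose, tol=1e-9)

    def test_objective_value_consistent_with_terms(self, optimized_fixture):
        assert np.isclose(
            optimized_fixture.objective_value,
            objective_value(optimized_fixture.terms, PAPER_WEIGHTS),
            atol=1e-9,
        )

    def test_watershed_margin_preserved(self, standard_case, optimized_fixture):
        sc = standard_case
        ws = sc["bone_lm"].watershed
        r, t = optimized_fixture.pose.matrix()
        for corner in (sc["plate_lm"].top_left, sc["plate_lm"].top_right):
            p = r @ corner + t
            wz = float(watershed_interp(ws, np.clip(p[1], ws[0, 1], ws[-1, 1]), 2))
            assert wz - p[2] >= 2.0 - 0.02

    def test_penetration_is_shallow_and_bounded(self, standard_case, optimized_fixture):
        from plateplan.mesh_core import SurfaceDistance

        sc = standard_case
        surf = SurfaceDistance(sc["bone_std"])
        r, t = optimized_fixture.pose.matrix()
        signed = surf.signed(sc["plate_std"].vertices @ r.T + t, band=8.0)
        pen = signed < 0
        assert pen.sum() <= 0.10 * sc["plate_std"].n_vertices
        if pen.any():
            assert signed[pen].min() >= -1.0

    def test_zero_weights_return_initial_pose(self, standard_case, initial_fixture):
        from plateplan import optimize_pose

        sc = standard_case
        res = optimize_pose(
            initial_fixture,
            sc["plate_std"],
            sc["plate_lm"],
            sc["bone_std"],
            sc["bone_lm"],
            ObjectiveWeights(0, 0, 0, 0, 0),
        )
        # every term but d_plate is switched off; d_plate still counts
        assert res.objective_value <= objective_value(
            compute_objective_terms(
                initial_fixture.pose, sc["plate_std"], sc["plate_lm"], sc["bone_std"]
            ),
            ObjectiveWeights(0, 0, 0, 0, 0),
        ) + 1e-9

    def test_reoptimizing_from_returned_pose_is_stable(
        self, standard_case, initial_fixture, optimized_fixture
    ):
        from plateplan import optimize_pose

        sc = standard_case
        again = optimize_pose(
            initial_fixture,
            sc["plate_std"],
            sc["plate_lm"],
            sc["bone_std"],
            sc["bone_lm"],
            PAPER_WEIGHTS,
            start=optimized_fixture.pose,
        )
        rel = abs(again.objective_value - optimized_fixture.objective_value)
        assert rel <= 0.01 * optimized_fixture.objective_value
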