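"""Landmark extraction: osteotomy-plane detection, midplane, alignment line,
watershed ridge extraction and plate landmarks, checked against analytic
oracles and generator ground truth."""

import numpy as np
import pytest
import trimesh

from plateplan import (
    Plane,
    TriMesh,
    bone_alignment_line,
    compute_midplane,
    compute_watershed,
    detect_osteotomy_planes,
    make_bone,
    make_plate,
    plate_landmarks,
    standardize_plate,
)
from plateplan.landmarks import (
    InsufficientDataError,
    NoIntersectionError,
    PlaneDetectionError,
    PlatePlanError,
    radius_width_at,
)
from plateplan.synthetic import SyntheticBoneSpec, SyntheticPlateSpec


def _grid_surface(xfun, ys, zs):
    """Triangulated height-field surface x = f(y, z) as a TriMesh."""
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    xx = xfun(yy, zz)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    ny, nz = len(ys), len(zs)
    faces = []
    for i in range(ny - 1):
        for j in range(nz - 1):
            a = i * nz + j
            faces.append((a, a + nz, a + nz + 1))
            faces.append((a, a + nz + 1, a + 1))
    return TriMesh(verts, np.asarray(faces))


class TestDetectOsteotomyPlanes:
    def test_recovers_generated_cut_planes(self, standard_case):
        gt = standard_case["bone_gt"]
        distal, proximal = detect_osteotomy_planes(standard_case["bone"])
        assert min(
            np.abs(distal.normal - gt.distal_plane.normal).max(),
            np.abs(distal.normal + gt.distal_plane.normal).max(),
        ) < 1e-6
        assert min(
            np.abs(proximal.normal - gt.proximal_plane.normal).max(),
            np.abs(proximal.normal + gt.proximal_plane.normal).max(),
        ) < 1e-6
        assert distal.point[2] > proximal.point[2]

    def test_uniform_mesh_has_no_clusters(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        with pytest.raises(PlaneDetectionError) as err:
            detect_osteotomy_planes(mesh)
        assert err.value.n_clusters == 0

    def test_three_cut_faces_rejected(self, standard_case):
        bone = standard_case["bone"]
        # glue a third fan-tessellated disk onto the mesh
        n = 24
        ang = 2 * np.pi * np.arange(n) / n
        ring = np.column_stack(
            [9.0 * np.cos(ang), 9.0 * np.sin(ang), np.full(n, -40.0)]
        )
        base = bone.n_vertices
        verts = np.vstack([bone.vertices, ring, [[0.0, 0.0, -40.0]]])
        extra = [(base + n, base + j, base + (j + 1) % n) for j in range(n)]
        mesh = TriMesh(verts, np.vstack([bone.faces, extra]))
        with pytest.raises(PlaneDetectionError) as err:
            detect_osteotomy_planes(mesh)
        assert err.value.n_clusters == 3

    def test_rigid_motion_covariance(self, standard_case, rng):
        from scipy.spatial.transform import Rotation

        bone = standard_case["bone"]
        d0, p0 = detect_osteotomy_planes(bone)
        r = Rotation.from_euler("xyz", [15, 40, -25], degrees=True).as_matrix()
        t = rng.normal(size=3) * 10
        d1, p1 = detect_osteotomy_planes(bone.transformed(r, t))
        assert np.abs(d1.point - (r @ d0.point + t)).max() < 1e-6
        assert min(
            np.abs(d1.normal - r @ d0.normal).max(),
            np.abs(d1.normal + r @ d0.normal).max(),
        ) < 1e-9


class TestMidplane:
    def test_parallel_planes(self):
        mid = compute_midplane(
            Plane([0, 0, 20], [0, 0, 1]), Plane([0, 0, 10], [0, 0, 1])
        )
        assert np.allclose(mid.point, [0, 0, 15])
        assert np.allclose(mid.normal, [0, 0, 1])

    def test_identical_planes(self):
        p = Plane([1, 2, 3], [0, 1, 0])
        mid = compute_midplane(p, p)
        assert np.allclose(mid.point, p.point)
        assert np.allclose(mid.normal, p.normal)

    def test_bisector_normal(self):
        n1 = np.array([np.sin(np.deg2rad(10)), 0, np.cos(np.deg2rad(10))])
        n2 = np.array([-np.sin(np.deg2rad(10)), 0, np.cos(np.deg2rad(10))])
        mid = compute_midplane(Plane([0, 0, 0], n1), Plane([0, 0, 2], n2))
        expect = (n1 + n2) / np.linalg.norm(n1 + n2)
        assert np.abs(mid.normal - expect).max() < 1e-9


class TestAlignmentLine:
    def test_axis_aligned_case(self, standard_case):
        bone = standard_case["bone_std"]
        mid = Plane([0, 0, 50], [0, 0, 1])
        point_p, line = bone_alignment_line(bone, mid, z_cut=40.0)
        proximal = bone.vertices[bone.vertices[:, 2] <= 40.0]
        assert np.isclose(point_p[0], proximal[:, 0].max())
        assert np.allclose(line.direction, [0, 1, 0], atol=1e-12)
        assert np.isclose(line.point[0], point_p[0])
        assert np.isclose(line.point[2], 50.0)

    def test_tilted_midplane_matches_closed_form(self, standard_case):
        bone = standard_case["bone_std"]
        ang = np.deg2rad(10)
        normal = np.array([np.sin(ang), 0, np.cos(ang)])
        mid = Plane([0, 0, 50], normal)
        point_p, line = bone_alignment_line(bone, mid, z_cut=40.0)
        # closed-form two-plane intersection of {x = P.x} and the midplane
        direction = np.cross(normal, [1.0, 0.0, 0.0])
        direction /= np.linalg.norm(direction)
        z_expect = (normal @ mid.point - normal[0] * point_p[0]) / normal[2]
        assert min(
            np.abs(line.direction - direction).max(),
            np.abs(line.direction + direction).max(),
        ) < 1e-9
        assert np.isclose(line.point[0], point_p[0], atol=1e-9)
        assert np.isclose(line.point[2], z_expect, atol=1e-9)

    def test_parallel_midplane_rejected(self, standard_case):
        with pytest.raises(NoIntersectionError):
            bone_alignment_line(
                standard_case["bone_std"], Plane([5, 0, 0], [1, 0, 0])
            )


class TestWatershed:
    def test_half_cylinder_analytic_ridge(self):
        # cylinder of radius 10, axis along Y: the ridge is x = 10, z = 5
        alphas = np.deg2rad(np.linspace(-80, 80, 400))
        ys = np.linspace(0, 30, 40)
        aa, yy = np.meshgrid(alphas, ys, indexing="ij")
        verts = np.column_stack(
            [10 * np.cos(aa).ravel(), yy.ravel(), 5 + 10 * np.sin(aa).ravel()]
        )
        faces = [[0, 1, 2], [0, 2, 3], [1, 2, 4], [2, 3, 4]]
        mesh = TriMesh(verts, np.asarray(faces))
        polyline, width = compute_watershed(mesh)
        # constant in Y within 1e-3; absolute values limited by the angular
        # sampling of the fixture (r * dalpha / 2)
        assert np.ptp(polyline[:, 0]) < 1e-3
        assert np.ptp(polyline[:, 2]) < 1e-3
        assert np.abs(polyline[:, 0] - 10.0).max() < 5e-3
        assert np.abs(polyline[:, 2] - 5.0).max() < 0.05
        assert width > 25

    def test_noisy_quadratic_ridge_recovered_within_3_sigma(self, rng):
        sigma = 0.05
        q = lambda y: 20.0 - 0.05 * y**2

        def xfun(yy, zz):
            return q(yy) - 0.2 * (zz - 10.0) ** 2 + rng.normal(0, sigma, yy.shape)

        mesh = _grid_surface(xfun, np.linspace(-10, 10, 81), np.linspace(5, 15, 41))
        polyline, _ = compute_watershed(mesh)
        assert np.abs(polyline[:, 0] - q(polyline[:, 1])).max() < 3 * sigma

    def test_z_band_excludes_outlier(self, rng):
        def xfun(yy, zz):
            return 20.0 - 0.05 * yy**2 - 0.2 * (zz - 10.0) ** 2

        mesh = _grid_surface(xfun, np.linspace(-10, 10, 41), np.linspace(5, 15, 21))
        n_clean = len(compute_watershed(mesh)[0])
        spike = np.vstack([mesh.vertices, [[30.0, 0.31, 20.0]]])  # z 10 above ridge
        spiked = TriMesh(spike, mesh.faces)
        n_spiked = len(compute_watershed(spiked)[0])
        assert n_spiked == n_clean - 1

    def test_monotone_in_y(self, standard_case):
        ws = standard_case["bone_lm"].watershed
        assert (np.diff(ws[:, 1]) > 0).all()

    def test_too_few_slices_rejected(self):
        verts = np.column_stack(
            [np.ones(8), np.repeat([0.0, 0.4], 4), np.tile([0, 1, 2, 3], 2)]
        )
        mesh = TriMesh(verts, np.asarray([[0, 1, 2], [1, 2, 3], [2, 3, 4], [3, 4, 5]]))
        with pytest.raises(InsufficientDataError):
            compute_watershed(mesh)


class TestPlateLandmarks:
    def test_corners_equal_ground_truth_exactly(self, plate_case):
        plate, gt = plate_case
        lm = plate_landmarks(plate)
        for key in ("top_left", "top_right", "bottom"):
            assert np.array_equal(getattr(lm, key), gt.corners[key])

    def test_symmetric_plate_has_symmetric_corners(self):
        plate, _ = make_plate(SyntheticPlateSpec(grid_jitter=0.0))
        lm = plate_landmarks(plate)
        assert np.isclose(abs(lm.top_left[1]), abs(lm.top_right[1]), atol=1e-6)

    def test_invariant_under_vertex_permutation(self, plate_case):
        plate, _ = plate_case
        rng = np.random.default_rng(5)
        perm = rng.permutation(plate.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = TriMesh(plate.vertices[perm], inv[plate.faces])
        lm0 = plate_landmarks(plate)
        lm1 = plate_landmarks(shuffled)
        for key in ("top_left", "top_right", "bottom"):
            assert np.array_equal(getattr(lm0, key), getattr(lm1, key))

    def test_rotated_then_standardized_landmarks_match(self, standard_case):
        from scipy.spatial.transform import Rotation

        plate = standard_case["plate"]
        lm0 = plate_landmarks(standard_case["plate_std"])
        r = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        lm1 = plate_landmarks(
            standardize_plate(plate.transformed(r, np.zeros(3))).standardized_mesh
        )
        for key in ("top_left", "top_right", "bottom"):
            assert np.abs(getattr(lm0, key) - getattr(lm1, key)).max() < 1e-6

    def test_invariants(self, standard_case):
        lm = standard_case["plate_lm"]
        assert lm.top_left[2] > lm.bottom[2]
        assert lm.top_right[2] > lm.bottom[2]
        d = lm.top_right - lm.top_left
        d = d / np.linalg.norm(d)
        assert abs(abs(lm.alignment_line.direction @ d) - 1) < 1e-9
        assert lm.plate_length > 50


class TestRadiusWidth:
    def test_width_at_cut_level_spans_the_section(self, standard_case):
        lm = standard_case["bone_lm"]
        assert 18 < lm.radius_width < 28
        assert lm.watershed_width > 15

    def test_missing_level_rejected(self, standard_case):
        with pytest.raises(PlatePlanError):
            radius_width_at(standard_case["bone_std"], 1e4)
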