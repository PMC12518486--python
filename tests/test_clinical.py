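"""Distal-segment extraction, registration, 6-DOF decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapecomplete import (SixDofError, TriangleMesh, ValidationError,
                           clinical_error, compose_6dof, cut_by_length_fraction,
                           decompose_6dof, distal_origin,
                           extract_distal_segment, register_distal)
from shapecomplete.geometry import apply_rigid
from shapecomplete.synthetic import apply_distal_rotation, \
    apply_distal_translation


class TestExtractSegment:
    def test_distal_12_percent_of_template(self, template_small):
        mesh, _, _ = template_small
        seg = extract_distal_segment(mesh, 0.12)
        assert (seg.vertices[:, 1] > 0.88 * 240 - 1e-9).all()
        assert seg.n_vertices > 0

    def test_half_cut_extent(self, template_small):
        mesh, _, _ = template_small
        seg = extract_distal_segment(mesh, 0.5)
        extent = np.ptp(seg.vertices[:, 1])
        assert extent == pytest.approx(0.5 * 240, rel=0.05)

    def test_faces_partition(self, template_small):
        mesh, _, _ = template_small
        _, dist = cut_by_length_fraction(mesh, 0.88)
        mask = dist.mask()[mesh.faces]
        fully_in = mask.all(axis=1).sum()
        fully_out = (~mask).all(axis=1).sum()
        straddling = mesh.n_faces - fully_in - fully_out
        seg = extract_distal_segment(mesh, 0.12)
        assert seg.n_faces == fully_in
        assert fully_in + fully_out + straddling == mesh.n_faces


class TestRegisterDistal:
    def test_identity_pair(self, template_small):
        mesh, _, _ = template_small
        seg = extract_distal_segment(mesh, 0.12)
        R, t = register_distal(seg, seg)
        assert np.abs(R - np.eye(3)).max() < 1e-6
        assert np.abs(t).max() < 1e-4

    def test_recovers_7_degree_rotation(self, template_small):
        mesh, _, _ = template_small
        seg = extract_distal_segment(mesh, 0.12)
        origin = seg.vertices.mean(axis=0)
        R_true = Rotation.from_euler("x", 7, degrees=True).as_matrix()
        t_true = origin - R_true @ origin
        rotated = TriangleMesh(apply_rigid(R_true, t_true, seg.vertices),
                               seg.faces)
        R, t = register_distal(rotated, seg)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(R @ R_true.T) - 1) / 2,
                                             -1, 1)))
        assert angle < 0.1

    def test_degenerate_segment_rejected(self):
        flat = TriangleMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                                      [1, 1, 0]]),
                            np.array([[0, 1, 2], [1, 3, 2]]))
        with pytest.raises(ValidationError, match="degenerate"):
            register_distal(flat, flat)


class TestDecompose:
    def test_identity_gives_all_zero(self):
        err = decompose_6dof(np.eye(3), np.zeros(3), np.array([0, 200.0, 0]))
        assert all(v == 0 for v in (err.phi_x, err.phi_z, err.phi_y,
                                    err.delta_x, err.delta_y, err.delta_z,
                                    err.angle_3d, err.dist_3d))

    def test_pure_translation_is_lengthening(self):
        origin = np.array([0, 200.0, 0])
        err = decompose_6dof(np.eye(3), np.array([0, 2.0, 0]), origin)
        assert err.delta_y == pytest.approx(2.0, abs=1e-12)
        assert err.phi_x == err.phi_z == err.phi_y == 0.0
        assert err.dist_3d == pytest.approx(2.0, abs=1e-12)

    def test_pure_x_rotation(self):
        origin = np.array([0, 200.0, 0])
        R = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        t = origin - R @ origin            # rotation about the distal origin
        err = decompose_6dof(R, t, origin)
        assert err.phi_x == pytest.approx(10.0, abs=1e-9)
        assert err.angle_3d == pytest.approx(10.0, abs=1e-9)
        assert abs(err.phi_z) < 1e-9 and abs(err.phi_y) < 1e-9
        assert err.dist_3d == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_compose_decompose_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        origin = np.array([1.0, 210.0, -2.0])
        err = SixDofError(*rng.uniform(-30, 30, 3), *rng.uniform(-5, 5, 3),
                          angle_3d=0.0, dist_3d=0.0)
        # normalise the derived fields
        R, t = compose_6dof(err, origin)
        back = decompose_6dof(R, t, origin)
        assert back.phi_x == pytest.approx(err.phi_x, abs=1e-9)
        assert back.phi_z == pytest.approx(err.phi_z, abs=1e-9)
        assert back.phi_y == pytest.approx(err.phi_y, abs=1e-9)
        assert back.delta_x == pytest.approx(err.delta_x, abs=1e-9)
        assert back.delta_y == pytest.approx(err.delta_y, abs=1e-9)
        assert back.delta_z == pytest.approx(err.delta_z, abs=1e-9)

    def test_dist3d_is_euclidean_norm_exactly(self):
        err = decompose_6dof(np.eye(3), np.array([1.0, 2.0, -2.0]),
                             np.zeros(3))
        assert err.dist_3d ** 2 == pytest.approx(
            err.delta_x ** 2 + err.delta_y ** 2 + err.delta_z ** 2, rel=1e-15)

    def test_angle3d_is_convention_free(self):
        rng = np.random.default_rng(3)
        R = Rotation.from_rotvec(np.deg2rad(17) * np.array([0.6, 0.64, 0.48])
                                 ).as_matrix()
        err = decompose_6dof(R, np.zeros(3), np.zeros(3))
        # axis-angle magnitude straight from the rotation, no Euler order
        expected = np.rad2deg(np.linalg.norm(Rotation.from_matrix(R).as_rotvec()))
        assert err.angle_3d == pytest.approx(expected, abs=1e-12)

    def test_gimbal_flagged(self):
        R = Rotation.from_euler("XZY", [5, 90, 3], degrees=True).as_matrix()
        err = decompose_6dof(R, np.zeros(3), np.zeros(3))
        assert err.gimbal_degenerate


class TestClinicalError:
    def test_identical_meshes_give_zero(self, template_small):
        mesh, _, _ = template_small
        err = clinical_error(mesh, mesh, 0.12)
        assert err.angle_3d < 1e-3
        assert err.dist_3d < 1e-3

    def test_five_degree_distal_tilt_recovered(self, template_small):
        mesh, _, _ = template_small
        tilted = apply_distal_rotation(mesh, 5.0, axis="z", fraction=0.88)
        err = clinical_error(tilted, mesh, 0.12)
        assert err.phi_z == pytest.approx(5.0, abs=0.5)
        assert err.angle_3d == pytest.approx(5.0, abs=0.5)

    def test_known_distal_shift_recovered(self, template_small):
        mesh, _, _ = template_small
        shifted = apply_distal_translation(mesh, [0.0, 2.0, 0.0], 0.88)
        err = clinical_error(shifted, mesh, 0.12)
        assert err.delta_y == pytest.approx(2.0, abs=0.3)

    def test_angle3d_dominates_single_axis_components(self, template_small):
        mesh, _, _ = template_small
        for axis, attr in (("x", "phi_x"), ("z", "phi_z")):
            rotated = apply_distal_rotation(mesh, 6.0, axis=axis, fraction=0.88)
            err = clinical_error(rotated, mesh, 0.12)
            assert err.angle_3d >= abs(getattr(err, attr)) - 1e-6

    def test_half_bone_comparison_mode(self, template_small):
        mesh, _, _ = template_small
        tilted = apply_distal_rotation(mesh, 5.0, axis="z", fraction=0.88)
        err = clinical_error(tilted, mesh, 0.5)
        # registering the whole distal half dilutes the distal-only tilt
        assert err.angle_3d < 5.0
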