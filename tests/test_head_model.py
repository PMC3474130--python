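"""Conductivity tensor construction and label-volume plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdcsteer.errors import ConfigurationError, InvalidParameterError
from tdcsteer.head_model import (
    AnisotropyField,
    ConductivityEntry,
    ConductivityTable,
    TissueLabelVolume,
    assemble_tensor_field,
    boundary_faces,
    build_tensor,
    default_conductivity_table,
    rotation_matrix,
    validate_model,
)

WM_LONG, WM_TRANS = 1.2, 0.12


def _volume_of(labels, names, spacing=(2.0, 2.0, 2.0)):
    return TissueLabelVolume(labels=np.asarray(labels, dtype=np.int16),
                             spacing=spacing, label_names=names)


class TestBuildTensor:
    def test_zero_angles_give_diagonal_white_matter_tensor(self):
        D = build_tensor(WM_LONG, WM_TRANS, (0.0, 0.0, 0.0))
        assert np.allclose(D, np.diag([WM_LONG, WM_TRANS, WM_TRANS]))

    @pytest.mark.parametrize("angles", [(0.1, 0.2, 0.3), (1.0, -2.0, 0.5), (np.pi, 0, np.pi / 3)])
    def test_isotropic_limit_is_rotation_invariant(self, angles):
        D = build_tensor(0.33, 0.33, angles)
        assert np.allclose(D, 0.33 * np.eye(3), atol=1e-14)

    def test_quarter_turn_about_z_moves_longitudinal_axis_to_y(self):
        # independent oracle: direct matrix product A^T D* A
        angles = (0.0, 0.0, np.pi / 2)
        A = rotation_matrix(angles)
        expected = A.T @ np.diag([WM_LONG, WM_TRANS, WM_TRANS]) @ A
        D = build_tensor(WM_LONG, WM_TRANS, angles)
        assert np.allclose(D, expected, atol=1e-12)
        w, v = np.linalg.eigh(D)
        long_axis = v[:, np.argmax(w)]
        # x-axis rotated by Rz(pi/2) lands on y
        assert np.isclose(abs(long_axis[1]), 1.0, atol=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(
        ax=st.floats(-3.1, 3.1), ay=st.floats(-3.1, 3.1), az=st.floats(-3.1, 3.1),
        sl=st.floats(0.2, 2.0), ratio=st.floats(0.05, 1.0),
    )
    def test_rotation_consistency_eigenvalues_and_trace(self, ax, ay, az, sl, ratio):
        st_ = sl * ratio
        D = build_tensor(sl, st_, (ax, ay, az))
        A = rotation_matrix((ax, ay, az))
        oracle = A.T @ np.diag([sl, st_, st_]) @ A
        assert np.allclose(D, oracle, atol=1e-12)
        assert np.allclose(np.sort(np.linalg.eigvalsh(D)), [st_, st_, sl], atol=1e-10)
        assert np.isclose(np.trace(D), sl + 2 * st_, atol=1e-12)

    @pytest.mark.parametrize(
        "sl,st_,angles",
        [(np.nan, 0.1, (0, 0, 0)), (1.0, np.inf, (0, 0, 0)), (1.0, 0.1, (np.nan, 0, 0)),
         (0.1, 1.0, (0, 0, 0)), (-1.0, -2.0, (0, 0, 0))],
    )
    def test_invalid_parameters_rejected(self, sl, st_, angles):
        with pytest.raises(InvalidParameterError):
            build_tensor(sl, st_, angles)


class TestConductivityTable:
    def test_default_table_reproduces_reference_values(self):
        table = default_conductivity_table()
        assert table["skin"].isotropic_sigma == 0.43
        assert table["cerebrospinal_fluid"].isotropic_sigma == 1.8
        assert table["cortical_bone"].isotropic_sigma == 5.52e-3
        assert table["cancelous_bone"].isotropic_sigma == 21.4e-3
        assert table["gray_matter"].isotropic_sigma == 0.1
        assert table["muscle"].isotropic_sigma == 0.16
        assert table["fat"].isotropic_sigma == 0.025
        assert table["blood"].isotropic_sigma == 0.67
        assert table["sclera"].isotropic_sigma == 0.5
        wm = table["white_matter"]
        assert wm.anisotropic
        assert (wm.sigma_longitudinal, wm.sigma_transverse) == (1.2, 0.12)

    def test_yaml_round_trip(self, tmp_path):
        table = default_conductivity_table()
        table.to_yaml(tmp_path / "t.yaml")
        back = ConductivityTable.from_yaml(tmp_path / "t.yaml")
        assert back.to_mapping() == table.to_mapping()

    def test_anisotropic_entry_requires_ordered_positive_pair(self):
        with pytest.raises(InvalidParameterError):
            ConductivityEntry(0.1, 0.2, anisotropic=True)
        with pytest.raises(InvalidParameterError):
            ConductivityEntry(0.1, 0.0, anisotropic=True)


class TestAssembleTensorField:
    def test_gray_matter_cube_is_scaled_identity(self):
        vol = _volume_of(np.full((4, 4, 4), 2), {2: "gray_matter"})
        field = assemble_tensor_field(vol, default_conductivity_table())
        assert np.allclose(field.tensors, 0.1 * np.eye(3))

    def test_air_volume_gives_zero_tensors(self):
        vol = _volume_of(np.zeros((3, 3, 3)), {})
        field = assemble_tensor_field(vol, default_conductivity_table())
        assert np.all(field.tensors == 0.0)

    def test_white_matter_random_angles_preserve_eigenvalue_multiset(self):
        rng = np.random.default_rng(42)
        labels = np.full((3, 3, 3), 5)
        vol = _volume_of(labels, {5: "white_matter"})
        aniso = AnisotropyField(angles=rng.uniform(-np.pi, np.pi, size=(3, 3, 3, 3)))
        field = assemble_tensor_field(vol, default_conductivity_table(), aniso)
        eigs = np.linalg.eigvalsh(field.tensors.reshape(-1, 3, 3))
        assert np.allclose(np.sort(eigs, axis=1), [WM_TRANS, WM_TRANS, WM_LONG], atol=1e-10)

    def test_missing_label_and_missing_angles_are_configuration_errors(self):
        vol = _volume_of(np.full((2, 2, 2), 9), {9: "mystery"})
        with pytest.raises(ConfigurationError):
            assemble_tensor_field(vol, default_conductivity_table())
        wm = _volume_of(np.full((2, 2, 2), 5), {5: "white_matter"})
        with pytest.raises(ConfigurationError):
            assemble_tensor_field(wm, default_conductivity_table())

    def test_deterministic_and_idempotent(self):
        vol = _volume_of(np.full((3, 3, 3), 2), {2: "gray_matter"})
        a = assemble_tensor_field(vol, default_conductivity_table())
        b = assemble_tensor_field(vol, default_conductivity_table())
        assert np.array_equal(a.tensors, b.tensors)


class TestValidateModel:
    def test_valid_grounded_block_passes(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[1:3, 1:3, 0:3] = 2
        vol = _volume_of(labels, {2: "gray_matter"})
        assert validate_model(vol, default_conductivity_table()).passed

    def test_unknown_label_is_named(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[1:3, 1:3, 0:3] = 7
        vol = _volume_of(labels, {7: "kryptonite"})
        report = validate_model(vol, default_conductivity_table())
        assert not report.passed
        assert any("7" in p for p in report.problems)

    def test_floating_head_flags_missing_base_plane(self):
        labels = np.zeros((4, 4, 5), dtype=np.int16)
        labels[1:3, 1:3, 2:4] = 2  # nothing on the lowest slice
        vol = _volume_of(labels, {2: "gray_matter"})
        report = validate_model(vol, default_conductivity_table())
        assert any("base plane" in p for p in report.problems)

    def test_disconnected_components_flagged(self):
        labels = np.zeros((7, 3, 3), dtype=np.int16)
        labels[0:2, 1, 0] = 2
        labels[5:7, 1, 0] = 2
        vol = _volume_of(labels, {2: "gray_matter"})
        report = validate_model(vol, default_conductivity_table())
        assert any("disconnected" in p for p in report.problems)


class TestBoundaryFaces:
    def test_unit_cube_voxel_has_six_faces_with_outward_normals(self):
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        labels[1, 1, 1] = 2
        vol = _volume_of(labels, {2: "gray_matter"})
        faces = boundary_faces(vol)
        assert len(faces) == 6
        assert np.allclose(faces.areas_mm2, 4.0)  # 2 mm spacing
        # outward normals point away from the voxel center
        rel = faces.centers_mm - np.array([3.0, 3.0, 3.0])
        assert np.all(np.einsum("ij,ij->i", rel, faces.normals) > 0)

    def test_face_count_matches_surface_of_block(self):
        labels = np.zeros((6, 5, 4), dtype=np.int16)
        labels[1:5, 1:4, 0:3] = 2
        vol = _volume_of(labels, {2: "gray_matter"})
        faces = boundary_faces(vol)
        # block of 4 x 3 x 3 voxels: surface faces = 2*(4*3 + 4*3 + 3*3)
        assert len(faces) == 2 * (12 + 12 + 9)
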