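"""Phantom generation and the analytic oracles."""

import numpy as np
import pytest

from tdcsteer.errors import ConfigurationError, InvalidParameterError
from tdcsteer.phantoms import (
    Blob,
    PhantomSpec,
    analytic_slab_field,
    analytic_sphere_potential,
    build_phantom,
    phantom_center_mm,
    truncated_shell_volume_mm3,
)


class TestSpherePhantom:
    def test_shell_volumes_match_truncated_analytic_volumes(self):
        spec = PhantomSpec(kind="sphere", voxel_mm=2.0)
        volume, _, _ = build_phantom(spec)
        h3 = spec.voxel_mm**3
        radii = [r for r, _ in spec.shells] + [0.0]
        cut = spec.truncation_fraction * radii[0]
        for label, (r_out, r_in) in enumerate(zip(radii, radii[1:]), start=1):
            analytic = truncated_shell_volume_mm3(r_out, r_in, cut)
            voxelized = float((volume.labels == label).sum()) * h3
            assert voxelized == pytest.approx(analytic, rel=0.05)

    def test_same_seed_is_bit_identical(self):
        spec = dict(kind="sphere", voxel_mm=4.0, anisotropic_core=True, seed=7)
        va, _, aa = build_phantom(PhantomSpec(**spec))
        vb, _, ab = build_phantom(PhantomSpec(**spec))
        assert np.array_equal(va.labels, vb.labels)
        assert np.array_equal(aa.angles, ab.angles)

    def test_zero_radius_blob_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(
                kind="sphere",
                target_blobs=(Blob(center_mm=(0, 0, 0), radius_mm=0.0, name="target"),),
            )

    def test_blob_outside_inner_shell_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(
                kind="sphere",
                target_blobs=(Blob(center_mm=(60, 0, 0), radius_mm=10.0, name="target"),),
            )

    def test_overlapping_target_avoid_blobs_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(
                kind="sphere",
                target_blobs=(Blob(center_mm=(0, 0, 10), radius_mm=10.0, name="target"),),
                avoid_blobs=(Blob(center_mm=(0, 0, -5), radius_mm=10.0, name="avoid"),),
            )

    def test_labels_are_radially_nested(self):
        spec = PhantomSpec(kind="sphere", voxel_mm=4.0)
        volume, _, _ = build_phantom(spec)
        center = phantom_center_mm(spec)
        # along rays from the center, the shell label index never decreases
        # (outer tissue never appears inside inner tissue)
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            radii = np.linspace(1.0, 79.0, 60)
            labels_on_ray = []
            for r in radii:
                p = center + d * r
                idx = tuple((p // spec.voxel_mm).astype(int))
                if all(0 <= i < s for i, s in zip(idx, volume.shape)):
                    lab = int(volume.labels[idx])
                    if 1 <= lab <= len(spec.shells):
                        labels_on_ray.append(lab)
            assert labels_on_ray == sorted(labels_on_ray, reverse=True)

    def test_base_plane_is_lowest_slice(self):
        spec = PhantomSpec(kind="sphere", voxel_mm=4.0)
        volume, _, _ = build_phantom(spec)
        assert volume.base_plane_index() == 0
        assert volume.nonair_mask[:, :, 0].any()


class TestSlabOracle:
    def test_current_density_is_current_over_area(self):
        J, _ = analytic_slab_field(1e-4, 1e-3, 0.1, 0.1)
        assert J == pytest.approx(10.0)

    def test_voltage_follows_ohms_law_and_sigma_scaling(self):
        J1, dV1 = analytic_slab_field(1e-4, 1e-3, 0.1, 0.1)
        assert dV1 == pytest.approx(10.0)
        J2, dV2 = analytic_slab_field(1e-4, 1e-3, 0.2, 0.1)
        assert J2 == pytest.approx(J1)
        assert dV2 == pytest.approx(dV1 / 2)

    @pytest.mark.parametrize("bad", [(-1e-4, 1e-3, 0.1, 0.1), (1e-4, 0.0, 0.1, 0.1),
                                     (1e-4, 1e-3, -0.1, 0.1), (1e-4, 1e-3, 0.1, np.inf)])
    def test_non_positive_or_non_finite_inputs_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            analytic_slab_field(*bad)


class TestSphereOracle:
    R, SIGMA = 0.08, 0.33

    def _surface_points(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(n, 3))
        return p / np.linalg.norm(p, axis=1, keepdims=True) * self.R

    def test_coincident_source_and_sink_cancel(self):
        pts = self._surface_points()
        sol = analytic_sphere_potential(
            self.R, self.SIGMA, np.array([[0, 0, 1.0], [0, 0, 1.0]]), 1e-3, pts
        )
        assert np.allclose(sol.values, 0.0)

    def test_antipodal_pair_is_antisymmetric_about_equator(self):
        pts = self._surface_points()
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        electrodes = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        top = analytic_sphere_potential(self.R, self.SIGMA, electrodes, 1e-3, pts)
        bottom = analytic_sphere_potential(self.R, self.SIGMA, electrodes, 1e-3, mirrored)
        assert np.allclose(top.values, -bottom.values, atol=1e-12)

    def test_reciprocity_swapping_electrodes_negates_potential(self):
        pts = self._surface_points()
        e = np.array([[0, 0, 1.0], [np.sin(1.0), 0, np.cos(1.0)]])
        fwd = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts)
        rev = analytic_sphere_potential(self.R, self.SIGMA, e[::-1], 1e-3, pts)
        assert np.allclose(fwd.values, -rev.values, atol=1e-14)

    def test_series_self_convergence_away_from_surface(self):
        # interior points: the truncated series converges geometrically there
        pts = self._surface_points() * 0.9
        e = np.array([[np.sin(0.5), 0, np.cos(0.5)], [-np.sin(0.5), 0, np.cos(0.5)]])
        lo = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts, order=200)
        hi = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts, order=400)
        scale = np.abs(hi.values).max()
        assert np.abs(lo.values - hi.values).max() / scale < 1e-6

    def test_truncated_series_approaches_closed_form(self):
        pts = self._surface_points() * 0.85
        e = np.array([[0, 0, 1.0], [1.0, 0, 0.0]])
        series = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts, order=300)
        closed = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts, order=None)
        scale = np.abs(closed.values).max()
        assert np.abs(series.values - closed.values).max() / scale < 1e-8

    def test_surface_truncation_emits_convergence_warning(self):
        pts = self._surface_points()
        e = np.array([[0, 0, 1.0], [1.0, 0, 0.0]])
        with pytest.warns(RuntimeWarning):
            analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts, order=50)

    def test_exterior_observation_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            analytic_sphere_potential(
                self.R, self.SIGMA, np.array([[0, 0, 1.0], [0, 1.0, 0]]), 1e-3,
                np.array([[0, 0, 2 * self.R]]),
            )

    def test_interior_samples_satisfy_discrete_laplace_equation(self):
        # 7-point Laplacian residual on a fine interior grid, away from electrodes
        e = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        h = 0.002
        xs = np.arange(-0.02, 0.021, h)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        sol = analytic_sphere_potential(self.R, self.SIGMA, e, 1e-3, pts)
        u = sol.values.reshape(X.shape)
        lap = (
            u[2:, 1:-1, 1:-1] + u[:-2, 1:-1, 1:-1]
            + u[1:-1, 2:, 1:-1] + u[1:-1, :-2, 1:-1]
            + u[1:-1, 1:-1, 2:] + u[1:-1, 1:-1, :-2]
            - 6 * u[1:-1, 1:-1, 1:-1]
        ) / h**2
        # normalize by the potential scale over the patch / characteristic length
        scale = np.abs(u).max() / h**2
        assert np.abs(lap).max() / scale < 1e-3
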