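"""Gradient tensors, principal decomposition, invariants, strain series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import muskstrain3d as m
from muskstrain3d.csrecon import VelocitySeries
from muskstrain3d.phantom import deformation_matrix
from muskstrain3d.tracking import DisplacementSeries


def _random_symmetric(rng, n=1):
    a = rng.standard_normal((n, 3, 3))
    return 0.5 * (a + np.swapaxes(a, -1, -2))


class TestGradientTensor:
    def test_uniform_field_zero_gradient(self):
        f = np.ones((6, 5, 4, 3)) * [1.0, -2.0, 0.5]
        F = m.gradient_tensor(f, (2.0, 2.0, 5.0))
        assert np.abs(F).max() == 0.0

    def test_linear_field_exact(self, rng):
        A = rng.standard_normal((3, 3)) * 0.1
        spacing = (2.0, 1.5, 5.0)
        axes = [np.arange(n) * d for n, d in zip((8, 7, 5), spacing)]
        X = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        u = np.einsum("ij,...j->...i", A, X)
        F = m.gradient_tensor(u, spacing)
        # F[i, j] = du_j/dx_i = A[j, i]
        np.testing.assert_allclose(F, np.broadcast_to(A.T, F.shape), atol=1e-12)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            m.gradient_tensor(np.zeros((6, 6, 2, 3)), (2, 2, 5))

    def test_phantom_gradient_converges_at_O_h2(self):
        # refine all three axes: the through-plane velocity picks up a
        # nonlinear z dependence via the deformation-map inverse
        errs = []
        for shape, sp in (((64, 48, 4), (2.0, 2.0, 5.0)),
                          ((128, 96, 8), (1.0, 1.0, 2.5))):
            grid = m.VoxelGrid(shape=shape, spacing=sp)
            truth = m.make_deformation(m.DeformationModel(), grid)
            # frame of fastest contraction (velocity vanishes on the plateau)
            pk = int(np.argmax(np.abs(np.diff(truth.envelope))))
            F = m.gradient_tensor(truth.velocity_cm_s[..., pk, :] * 10.0,
                                  grid.spacing)
            SR = 0.5 * (F + np.swapaxes(F, -1, -2))
            err = np.abs(SR - truth.strain_rate_per_s[..., pk, :, :])
            # interior only: boundary differences are one-sided (O(h))
            errs.append(np.sqrt((err[2:-2, 2:-2, 1:-1] ** 2).mean()))
        assert errs[1] < errs[0] / 3.0


class TestSymmetrizeDiagonalize:
    def test_zero_tensor(self):
        pd = m.symmetrize_diagonalize(np.zeros((3, 3)))
        np.testing.assert_array_equal(pd.eigenvalues, 0.0)

    def test_eigenvalue_labeling_convention(self):
        """Eigenvalues of diag(-0.420, -0.001, 0.697) label as
        fiber/out-plane/in-plane in that order."""
        T = np.diag([-0.420, -0.001, 0.697])
        pd = m.symmetrize_diagonalize(T)
        assert pd.fiber == pytest.approx(-0.420)
        assert pd.out_plane == pytest.approx(-0.001)
        assert pd.in_plane == pytest.approx(0.697)

    def test_reconstruction_from_decomposition(self, rng):
        T = _random_symmetric(rng, 20)
        pd = m.symmetrize_diagonalize(T)
        rebuilt = np.einsum(
            "...ik,...k,...jk->...ij", pd.eigenvectors, pd.eigenvalues,
            pd.eigenvectors,
        )
        np.testing.assert_allclose(rebuilt, T, atol=1e-12)

    def test_eigenvectors_orthonormal_and_sign_fixed(self, rng):
        pd = m.symmetrize_diagonalize(_random_symmetric(rng, 10))
        eye = np.einsum("...ki,...kj->...ij", pd.eigenvectors, pd.eigenvectors)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape),
                                   atol=1e-10)
        biggest = np.take_along_axis(
            pd.eigenvectors,
            np.argmax(np.abs(pd.eigenvectors), axis=-2)[..., None, :],
            axis=-2,
        )[..., 0, :]
        assert (biggest > 0).all()

    def test_nonfinite_rejected(self):
        T = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            m.symmetrize_diagonalize(T)

    def test_fiber_eigenvector_aligns_with_fiber_axis(self):
        model = m.DeformationModel(fiber_angle_deg=30.0)
        A = deformation_matrix(model)
        pd = m.symmetrize_diagonalize(A)
        th = np.deg2rad(30.0)
        expected = np.array([np.cos(th), np.sin(th), 0.0])
        assert abs(np.dot(pd.eigenvectors[:, 0], expected)) == pytest.approx(1.0)


class TestInvariants:
    def test_isotropic_tensor_has_zero_shear(self):
        assert m.max_shear(0.37 * np.eye(3)) == pytest.approx(0.0)

    def test_worked_example(self):
        T = np.diag([-0.420, -0.001, 0.697])
        assert m.max_shear(T) == pytest.approx(0.9215, abs=5e-5)

    def test_uniaxial_closed_form(self):
        a = 0.3
        T = np.diag([-a, 0.0, 0.0])
        assert m.max_shear(T) == pytest.approx(2 * np.sqrt(2) / 3 * a)

    def test_volumetric_examples(self, rng):
        assert m.volumetric(np.diag([-0.4, 0.0, 0.3])) == pytest.approx(-0.1)
        T = _random_symmetric(rng, 15)
        np.testing.assert_allclose(
            m.volumetric(T), np.linalg.eigvalsh(T).sum(axis=-1), atol=1e-12
        )

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        T = _random_symmetric(rng)[0]
        R = Rotation.random(random_state=int(seed % 2**31)).as_matrix()
        Tr = R @ T @ R.T
        assert abs(m.max_shear(T) - m.max_shear(Tr)) < 1e-10
        assert abs(m.volumetric(T) - m.volumetric(Tr)) < 1e-10
        np.testing.assert_allclose(
            np.linalg.eigvalsh(T), np.linalg.eigvalsh(Tr), atol=1e-10
        )


class TestStrainSeries:
    def _disp(self, u, spacing=(2.0, 2.0, 5.0)):
        return DisplacementSeries(
            displacement=u, positions=np.zeros_like(u), spacing_mm=spacing,
            frame_interval_ms=142.0,
            out_of_fov=np.zeros(u.shape[:3], dtype=bool),
        )

    def test_rigid_translation_zero_strain(self):
        u = np.zeros((6, 6, 3, 4, 3))
        u[..., 1:, :] = [1.0, -2.0, 0.5]
        L = m.strain_series(self._disp(u))
        assert np.abs(L.tensor).max() < 1e-12

    def test_uniaxial_stretch(self):
        eps = 0.05
        shape = (8, 6, 3)
        y = np.arange(shape[0]) * 2.0
        u = np.zeros(shape + (3, 3))
        u[..., 2, 0] = eps * y[:, None, None]  # u_y = eps*y at frame 3
        L = m.strain_series(self._disp(u))
        np.testing.assert_allclose(L.tensor[..., 2, 0, 0], eps, atol=1e-12)
        assert np.abs(L.tensor[..., 2, 1, 1]).max() < 1e-12
        assert np.all(L.tensor[..., 0, :, :] == 0)

    def test_green_lagrange_adds_quadratic_term(self):
        eps = 0.2
        shape = (6, 6, 3)
        y = np.arange(shape[0]) * 1.0
        u = np.zeros(shape + (2, 3))
        u[..., 1, 0] = eps * y[:, None, None]
        disp = self._disp(u, spacing=(1.0, 1.0, 5.0))
        gl = m.strain_series(disp, definition="green-lagrange")
        np.testing.assert_allclose(
            gl.tensor[..., 1, 0, 0], eps + 0.5 * eps**2, atol=1e-12
        )

    def test_phantom_strain_recovery(self, truth):
        from muskstrain3d.tracking import track

        series = VelocitySeries(
            velocity=truth.velocity_cm_s,
            magnitude=np.ones(truth.velocity_cm_s.shape[:4]),
            spacing_mm=truth.grid.spacing,
            frame_interval_ms=truth.frame_interval_ms,
            venc_cm_s=10.0,
        )
        L = m.strain_series(track(series))
        pk = int(np.argmax(truth.envelope))
        err = L.tensor[..., pk, :, :] - truth.strain[..., pk, :, :]
        rmse = np.sqrt((err[truth.muscle_mask] ** 2).mean())
        assert rmse < 0.02

    def test_unreferenced_displacement_rejected(self):
        u = np.ones((6, 6, 3, 4, 3))
        with pytest.raises(ValueError, match="frame 1"):
            m.strain_series(self._disp(u))


class TestIncompressibility:
    def test_median_lvol_small_at_all_frames(self, truth):
        """The phantom's principal strains sum to zero; tracking + gradient
        estimation must keep the median |L_vol| over the muscle below 0.02
        at every frame."""
        from muskstrain3d.tracking import track

        series = VelocitySeries(
            velocity=truth.velocity_cm_s,
            magnitude=np.ones(truth.velocity_cm_s.shape[:4]),
            spacing_mm=truth.grid.spacing,
            frame_interval_ms=truth.frame_interval_ms,
            venc_cm_s=10.0,
        )
        L = m.strain_series(track(series))
        lvol = m.volumetric(L.tensor)[truth.muscle_mask]
        assert np.median(np.abs(lvol), axis=0).max() < 0.02


class TestTransverseAnisotropy:
    def test_out_plane_much_smaller_than_in_plane(self, truth):
        pk = int(np.argmax(truth.envelope))
        pd = m.symmetrize_diagonalize(truth.strain[truth.muscle_mask][:, pk])
        ratio = np.abs(pd.out_plane) / np.abs(pd.in_plane)
        assert ratio.max() < 0.1

    def test_strain_rate_peaks_before_strain(self, truth):
        sr_course = np.array([
            np.abs(m.symmetrize_diagonalize(
                truth.strain_rate_per_s[truth.muscle_mask][:, t]).fiber).mean()
            for t in range(truth.model.n_frames)
        ])
        l_course = np.array([
            np.abs(m.symmetrize_diagonalize(
                truth.strain[truth.muscle_mask][:, t]).fiber).mean()
            for t in range(truth.model.n_frames)
        ])
        assert np.argmax(sr_course) < np.argmax(l_course)
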