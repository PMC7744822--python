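"""Phantom generator: analytic kinematics, k-space synthesis, force curves."""

import numpy as np
import pytest

import muskstrain3d as m
from muskstrain3d.phantom import deformation_matrix, temporal_envelope
from muskstrain3d.tensors import gradient_tensor

from conftest import uniform_model


class TestDeformation:
    def test_zero_amplitude_gives_identity(self, small_grid):
        model = m.DeformationModel(amplitude_fiber=0.0, n_frames=5)
        truth = m.make_deformation(model, small_grid)
        assert np.all(truth.velocity_cm_s == 0)
        assert np.all(truth.displacement_mm == 0)
        assert np.all(truth.strain == 0)

    def test_uniform_linear_field_has_constant_strain(self, small_grid):
        model = uniform_model(amplitude=-0.1, angle=20.0)
        truth = m.make_deformation(model, small_grid)
        A = deformation_matrix(model)
        sym = 0.5 * (A + A.T)
        pk = int(np.argmax(truth.envelope))
        gmax = truth.envelope[pk]
        np.testing.assert_allclose(
            truth.strain[..., pk, :, :],
            np.broadcast_to(gmax * sym, truth.strain.shape[:3] + (3, 3)),
            atol=1e-12,
        )

    def test_incompressible_construction_is_traceless(self, small_grid):
        # principal strains sum to zero; with a FOV-wide plateau the strain
        # trace vanishes identically at every voxel and frame
        truth = m.make_deformation(uniform_model(), small_grid)
        tr = np.trace(truth.strain, axis1=-2, axis2=-1)
        assert np.abs(tr).max() < 1e-14

    def test_displacement_zero_at_first_and_last_frame(self, truth):
        assert np.all(truth.displacement_mm[..., 0, :] == 0)
        assert np.abs(truth.displacement_mm[..., -1, :]).max() < 1e-8

    def test_peak_contractile_strain_equals_amplitude(self, truth, model):
        pk = int(np.argmax(truth.envelope))
        vals = np.linalg.eigvalsh(truth.strain[..., pk, :, :][truth.muscle_mask])
        np.testing.assert_allclose(vals[:, 0], model.amplitude_fiber, atol=1e-12)

    def test_analytic_strain_matches_finite_differences_at_O_h2(self, model):
        # halving the grid spacing must cut the finite-difference error ~4x
        errs = []
        for shape, sp in (((64, 48, 3), (2.0, 2.0, 5.0)),
                          ((128, 96, 3), (1.0, 1.0, 5.0))):
            grid = m.VoxelGrid(shape=shape, spacing=sp)
            truth = m.make_deformation(model, grid)
            pk = int(np.argmax(truth.envelope))
            F = gradient_tensor(truth.displacement_mm[..., pk, :], grid.spacing)
            fd = 0.5 * (F + np.swapaxes(F, -1, -2))
            err = np.abs(fd - truth.strain[..., pk, :, :])
            # interior only: boundary differences are one-sided (O(h))
            errs.append(err[2:-2, 2:-2, :].max())
        assert errs[1] < errs[0] / 3.0

    def test_velocity_is_time_derivative_of_displacement(self, small_truth):
        # at frame 0 the deformation map is the identity, so the Eulerian
        # velocity on the grid equals the forward difference of the
        # Lagrangian displacement exactly
        dt_s = small_truth.frame_interval_ms / 1000.0
        u = small_truth.displacement_mm
        fd = (u[..., 1, :] - u[..., 0, :]) / dt_s / 10.0  # cm/s
        assert np.abs(small_truth.velocity_cm_s[..., 0, :] - fd).max() < 1e-9

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate|at least 3"):
            m.VoxelGrid(shape=(64, 48, 2))

    def test_positive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            m.DeformationModel(amplitude_fiber=0.1)


class TestTemporalEnvelope:
    def test_cyclic_closure_and_plateau(self):
        g = temporal_envelope(17)
        assert g[0] == 0 and g[-1] == 0
        assert g.max() == 1.0
        assert np.all((g >= 0) & (g <= 1))


class TestKSpaceEncoding:
    def test_full_sampling_roundtrip_per_coil(self, small_truth):
        params = m.AcquisitionParams(cs_factor=1.0, matrix=(32, 24))
        kset = m.encode_kspace(
            small_truth.velocity_cm_s, small_truth.magnitude, params, seed=0
        )
        assert kset.mask.all()
        # inverse FFT of any coil recovers the sensitivity-weighted image
        coil = 3
        img = np.fft.fftshift(
            np.fft.ifft2(
                np.fft.ifftshift(kset.data[coil, :, :, 1, 0, 0], axes=(0, 1)),
                axes=(0, 1), norm="ortho",
            ),
            axes=(0, 1),
        )
        expected = kset.true_sensitivities[coil] * small_truth.magnitude[:, :, 1]
        np.testing.assert_allclose(img, expected, atol=1e-12)

    def test_encoded_phase_is_pi_v_over_venc(self, small_truth):
        params = m.AcquisitionParams(cs_factor=1.0, matrix=(32, 24))
        vel = np.zeros_like(small_truth.velocity_cm_s)
        vel[..., 0] = params.venc_cm_s  # v_y = VENC everywhere
        kset = m.encode_kspace(vel, small_truth.magnitude, params, seed=0)
        img = np.fft.fftshift(
            np.fft.ifft2(
                np.fft.ifftshift(kset.data[0, :, :, 1, 0, 1], axes=(0, 1)),
                axes=(0, 1), norm="ortho",
            ),
            axes=(0, 1),
        )
        ref = kset.true_sensitivities[0] * small_truth.magnitude[:, :, 1]
        keep = np.abs(ref) > 1e-3
        phases = np.angle(img[keep] * np.conj(ref[keep]))
        assert np.abs(np.abs(phases) - np.pi).max() < 1e-6

    def test_sampled_line_count_at_cs4(self):
        mask = m.make_mask(n_ky=192, cs_factor=4, center_fraction=8 / 192,
                           n_frames=3, seed=0)
        assert mask.sum(axis=0).tolist() == [48, 48, 48]

    def test_velocity_beyond_venc_warns(self, small_truth):
        params = m.AcquisitionParams(cs_factor=1.0, matrix=(32, 24))
        vel = np.full_like(small_truth.velocity_cm_s, 2 * params.venc_cm_s)
        with pytest.warns(RuntimeWarning, match="VENC"):
            m.encode_kspace(vel, small_truth.magnitude, params, seed=0)

    def test_coil_sensitivities_sum_of_squares_one(self):
        maps = m.coil_sensitivities((32, 24), 8)
        sos = (np.abs(maps) ** 2).sum(axis=0)
        np.testing.assert_allclose(sos, 1.0, atol=1e-12)


class TestForceCurve:
    def test_noiseless_peak_matches_target(self):
        fc = m.make_force_curve(60.0, 330.0, n_cycles=4, noise_sd=0.0)
        np.testing.assert_allclose(fc.per_cycle_peaks(), 198.0, rtol=1e-6)

    def test_peak_scales_linearly_with_target(self):
        f30 = m.make_force_curve(30.0, 300.0, n_cycles=2)
        f60 = m.make_force_curve(60.0, 300.0, n_cycles=2)
        np.testing.assert_allclose(
            f60.per_cycle_peaks(), 2 * f30.per_cycle_peaks(), rtol=1e-9
        )

    def test_duration_arithmetic(self):
        fc = m.make_force_curve(60.0, 330.0, n_cycles=26, cycle_duration_s=2.4)
        assert fc.time_s[-1] == pytest.approx(62.4 - 1 / 200.0, abs=1e-9)
        assert fc.time_s.size == round(26 * 2.4 * 200)

    def test_force_nonnegative_with_noise(self):
        fc = m.make_force_curve(30.0, 300.0, n_cycles=3, noise_sd=25.0, seed=7)
        assert fc.force_n.min() >= 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m.make_force_curve(0.0, 300.0)
        with pytest.raises(ValueError):
            m.make_force_curve(50.0, 300.0, noise_sd=-1.0)
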