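"""Curvilinear Gaussian impulses, gauge-derivative kernels, tensor patches."""

import numpy as np
import pytest
from scipy.signal import fftconvolve
from scipy.spatial.transform import Rotation

from vesseltrees.kernels import (
    GaussianSwirlParams,
    _nearest_rotation,
    build_degenerate_kernels,
    build_slogs_kernel,
    build_tensor_patch,
    eval_gamma,
    expm_field,
    logm_field,
    steer_kernel,
)


def _gamma_reference(x, sigma, c):
    """Independent term-by-term evaluation of the warped trivariate Gaussian."""
    x1, x2, x3 = x
    X = [x1, x2 + c[0] * x1 + c[1] * x1**2, x3 + c[2] * x1**3]
    out = 1.0
    for Xd, sd in zip(X, sigma):
        out *= np.exp(-(Xd**2) / (2 * sd**2)) / np.sqrt(2 * np.pi * sd**2)
    return out


class TestImpulse:
    def test_peak_value_is_separable_gaussian_norm(self):
        sigma = (2.0, 0.9, 0.6)
        p = GaussianSwirlParams(sigma)
        expected = np.prod([(2 * np.pi * s**2) ** -0.5 for s in sigma])
        assert eval_gamma((0, 0, 0), p) == pytest.approx(expected, rel=1e-12)

    def test_shear_moves_the_midline(self):
        c0 = 0.4
        p_shear = GaussianSwirlParams((2.0, 0.7, 0.7), (c0, 0.0, 0.0))
        p_straight = GaussianSwirlParams((2.0, 0.7, 0.7))
        for x1 in [-2.0, -0.5, 1.0, 2.5]:
            assert eval_gamma((x1, -c0 * x1, 0.0), p_shear) == pytest.approx(
                eval_gamma((x1, 0.0, 0.0), p_straight), rel=1e-12
            )

    def test_matches_termwise_reference(self, rng):
        for _ in range(30):
            sigma = tuple(rng.uniform(0.5, 3.0, 3))
            c = tuple(rng.uniform(-0.3, 0.3, 3))
            x = rng.uniform(-3, 3, 3)
            got = eval_gamma(x, GaussianSwirlParams(sigma, c))
            assert got == pytest.approx(_gamma_reference(x, sigma, c), rel=1e-10)
            assert got > 0

    @pytest.mark.parametrize("sigma", [(0.0, 1, 1), (-1, 1, 1), (1, np.nan, 1)])
    def test_invalid_sigma_rejected(self, sigma):
        with pytest.raises(ValueError):
            GaussianSwirlParams(sigma)


class TestGaugeKernel:
    def test_modulation_coefficients(self, tube_params):
        """At the center each gamma_l is 1/3; elsewhere they sum to one."""
        from vesseltrees.kernels import _gamma_grad_hess, _sorted_eigh, _support_grid

        x = _support_grid(5)
        g, grad, H = _gamma_grad_hess(x, tube_params)
        lam, Q = _sorted_eigh(H)
        gn2 = np.sum(grad**2, axis=-1)
        proj = np.einsum("...j,...jl->...l", grad, Q)
        center = (5, 5, 5)
        assert gn2[center] == pytest.approx(0.0, abs=1e-300)
        nz = np.sqrt(gn2) > 1e-12 * np.sqrt(gn2.max())
        gam = proj[nz] ** 2 / gn2[nz][..., None]
        np.testing.assert_allclose(gam.sum(axis=-1), 1.0, atol=1e-9)

    def test_matches_finite_difference_gauge_second_derivative(self, tube_params):
        kern = build_slogs_kernel(tube_params)
        from vesseltrees.kernels import _gamma_grad_hess, _support_grid

        x = _support_grid(5)
        _, grad, _ = _gamma_grad_hess(x, tube_params)
        nrm = np.linalg.norm(grad, axis=-1, keepdims=True)
        w = np.where(nrm > 1e-15, grad / np.maximum(nrm, 1e-300), 0.0)
        h = 1e-3
        fd = (
            eval_gamma(x + h * w, tube_params)
            - 2 * eval_gamma(x, tube_params)
            + eval_gamma(x - h * w, tube_params)
        ) / h**2
        fd -= fd.mean()  # the stored kernel is DC-free
        nz = nrm[..., 0] > 1e-12 * nrm.max()
        err = np.abs(kern.kernel - fd)[nz].max() / np.abs(kern.kernel).max()
        assert err < 1e-3

    def test_kernel_is_zero_mean(self, tube_kernel, curved_kernel):
        for k in (tube_kernel, curved_kernel):
            assert abs(k.kernel.mean()) <= 1e-3 * np.abs(k.kernel).max()

    def test_impulse_positive_and_basis_rotation(self, curved_kernel):
        assert np.all(curved_kernel.impulse > 0)
        B = curved_kernel.orientation_basis
        np.testing.assert_allclose(B @ B.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(B) == pytest.approx(1.0, abs=1e-10)


class TestTensorPatch:
    def test_isotropic_impulse_gives_identity_tensors(self):
        patch = build_tensor_patch(GaussianSwirlParams((1.3, 1.3, 1.3)))
        np.testing.assert_allclose(patch.six_components, 0.0, atol=1e-9)

    def test_unit_determinant_everywhere(self, tube_kernel, curved_kernel):
        for k in (tube_kernel, curved_kernel):
            det = np.linalg.det(k.tensor_patch.euclidean())
            np.testing.assert_allclose(det, 1.0, atol=1e-6)

    def test_semiaxis_ratios_match_direct_eigendecomposition(self, tube_params):
        from vesseltrees.kernels import _neglog_gamma_hess, _support_grid

        patch = build_tensor_patch(tube_params)
        T = patch.euclidean()
        x = _support_grid(5)
        Ht = _neglog_gamma_hess(x, tube_params)
        lam = np.sort(np.abs(np.linalg.eigvalsh(Ht)), axis=-1)
        psi = np.stack(
            [lam[..., 0] / np.sqrt(lam[..., 1] * lam[..., 2]),
             lam[..., 1] / lam[..., 2],
             np.ones(lam.shape[:-1])], axis=-1
        )
        psi /= np.prod(psi, axis=-1, keepdims=True) ** (1 / 3)
        got = np.sort(np.linalg.eigvalsh(T), axis=-1)
        np.testing.assert_allclose(got, np.sort(psi, axis=-1), rtol=1e-6)

    def test_log_euclidean_round_trip(self, curved_kernel):
        six = curved_kernel.tensor_patch.six_components
        np.testing.assert_allclose(logm_field(expm_field(six)), six, atol=1e-9)


class TestDegenerateKernels:
    def test_delta_prefers_step_edges(self):
        dlog, _ = build_degenerate_kernels()
        step = np.zeros((21, 21, 21))
        step[10:] = 1.0
        const = np.ones((21, 21, 21))
        r_step = np.abs(fftconvolve(step, dlog, mode="valid")).max()
        r_const = np.abs(fftconvolve(const, dlog, mode="valid")).max()
        assert r_step > 10 * max(r_const, 1e-30)

    def test_nu_prefers_homogeneous_regions(self, rng):
        _, nlog = build_degenerate_kernels()
        const = np.ones((21, 21, 21))
        noise = rng.normal(0.0, 1.0, (21, 21, 21))
        r_const = np.abs(fftconvolve(const, nlog, mode="valid")).mean()
        r_noise = np.abs(fftconvolve(noise, nlog, mode="valid")).mean()
        assert r_const > r_noise

    def test_scalar_only(self):
        from vesseltrees.kernels import default_dictionary

        d = default_dictionary()
        assert d.delta_log.ndim == 3 and d.nu_log.ndim == 3
        # no tensor companion exists for the degenerate pair by construction
        assert not hasattr(d.delta_log, "tensor_patch")


class TestSteering:
    def test_identity_is_a_no_op(self, tube_kernel):
        out = steer_kernel(tube_kernel, tube_kernel.orientation_basis)
        assert out is tube_kernel

    def test_round_trip_recovers_original(self, curved_kernel):
        R = Rotation.from_euler("xyz", [35, -50, 20], degrees=True).as_matrix()
        B = _nearest_rotation(R @ curved_kernel.orientation_basis)
        back = steer_kernel(steer_kernel(curved_kernel, B),
                            curved_kernel.orientation_basis)
        rel = np.linalg.norm(back.kernel - curved_kernel.kernel)
        assert rel / np.linalg.norm(curved_kernel.kernel) <= 5e-2

    def test_norm_preserved_and_tensors_stay_unit_det(self, tube_kernel):
        R = Rotation.from_euler("zyx", [72, 31, -15], degrees=True).as_matrix()
        B = _nearest_rotation(R @ tube_kernel.orientation_basis)
        st = steer_kernel(tube_kernel, B)
        n0 = np.linalg.norm(tube_kernel.kernel)
        assert abs(np.linalg.norm(st.kernel) - n0) / n0 <= 0.05
        np.testing.assert_allclose(
            np.linalg.det(st.tensor_patch.euclidean()), 1.0, atol=1e-6
        )

    def test_steered_response_follows_the_rotated_tube(self, tube_kernel):
        from vesseltrees.orientations import complete_basis
        from vesseltrees.synthetic import straight_tube_phantom

        d_rot = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        _, vol_axis = straight_tube_phantom(24, 2, (1, 0, 0), (40, 40, 40))
        _, vol_rot = straight_tube_phantom(24, 2, d_rot, (40, 40, 40))
        st = steer_kernel(tube_kernel, complete_basis(d_rot))
        r_axis = fftconvolve(vol_axis.data, tube_kernel.kernel, mode="same").max()
        r_rot = fftconvolve(vol_rot.data, st.kernel, mode="same").max()
        assert abs(r_rot - r_axis) / r_axis < 0.05

    def test_invalid_basis_rejected(self, tube_kernel):
        with pytest.raises(ValueError):
            steer_kernel(tube_kernel, np.eye(3) * 2.0)
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            steer_kernel(tube_kernel, refl)
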