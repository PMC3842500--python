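import numpy as np
import pytest

import pictract as pt
from pictract.csd import CSDFitter, angular_resolution_sweep
from pictract.sphere import delta_sh, sh_basis, sphere_points


def two_tensor_signal(dirs, b, angle_deg, lambda_par=1.7e-3, lambda_perp=3e-4):
    a = np.radians(angle_deg)
    u1 = np.array([0.0, 0.0, 1.0])
    u2 = np.array([np.sin(a), 0.0, np.cos(a)])
    dl = lambda_par - lambda_perp
    return (
        0.5 * np.exp(-b * (lambda_perp + dl * (dirs @ u1) ** 2))
        + 0.5 * np.exp(-b * (lambda_perp + dl * (dirs @ u2) ** 2))
    ), u1, u2


class TestResponse:
    def test_reconvolved_response_matches_masked_mean_signal(
        self, straight_dwi, straight_truth, straight_response, scheme61
    ):
        """Reconvolving the estimated response with a delta FOD along z
        reproduces the masked mean signal up to the content the lmax = 8
        band cannot carry (the l >= 10 part of the tensor signal, ~1e-4
        relative at b = 1200)."""
        w = scheme61.b_weighted
        sig = straight_dwi.signal[straight_truth.single_fibre_mask()]
        b0 = sig[:, ~w].mean(axis=1)
        mean_sig = (sig[:, w] / b0[:, None]).mean(axis=0)
        k = straight_response.convolution_factors(8)
        pred = sh_basis(8, scheme61.directions[w]) @ (
            delta_sh(np.array([0.0, 0.0, 1.0]), 8) * k
        )
        rel = np.abs(pred - mean_sig).max() / mean_sig.max()
        assert rel < 1e-3

    def test_isotropic_voxels_give_zonal_dc_only(self, scheme61):
        empty = pt.PhantomTruth(shape=(6, 6, 6), voxel_size=1.0)
        dwi = pt.simulate_dwi(
            empty, scheme61, pt.TissueModel(snr=float("inf")), mask_dilation=-1
        )
        resp = pt.estimate_response(
            dwi, np.ones((6, 6, 6), bool), np.array([0.0, 0, 1.0])
        )
        assert np.all(np.abs(resp.zonal[1:]) < 1e-10 * resp.zonal[0])

    def test_l0_coefficient_is_sphere_average_times_sqrt_4pi(self):
        """Independent quadrature oracle: project the closed-form tensor
        signal on a dense sphere and compare the l = 0 coefficient."""
        gt = pt.make_gradient_scheme(300, 1200.0, seed=3)
        truth = pt.make_bundle_phantom(
            "straight", shape=(10, 10, 20), tube_radius=1.5
        )
        dwi = pt.simulate_dwi(truth, gt, pt.TissueModel(snr=float("inf")))
        resp = pt.estimate_response(
            dwi, truth.single_fibre_mask(), np.array([0.0, 0, 1.0])
        )
        dense = sphere_points(20000)
        model = pt.TissueModel(snr=float("inf"))
        dl = model.lambda_parallel - model.lambda_perp
        savg = np.exp(-1200.0 * (model.lambda_perp + dl * dense[:, 2] ** 2)).mean()
        assert np.isclose(resp.zonal[0], savg * np.sqrt(4 * np.pi), rtol=1e-4)

    def test_empty_mask_rejected(self, straight_dwi):
        with pytest.raises(ValueError, match="no single-fibre voxels"):
            pt.estimate_response(
                straight_dwi,
                np.zeros(straight_dwi.signal.shape[:3], bool),
                np.array([0.0, 0, 1.0]),
            )

    def test_analytic_tensor_response_matches_estimated(
        self, straight_response
    ):
        analytic = pt.tensor_response(1200.0)
        assert np.allclose(
            analytic.zonal, straight_response.zonal, atol=2e-4
        )


class TestFitCSD:
    def test_kernel_deconvolution_gives_single_peak_on_axis(self, scheme61):
        resp = pt.tensor_response(1200.0)
        w = scheme61.b_weighted
        # signal synthesised as the response itself, aligned with z
        sig_w = sh_basis(8, scheme61.directions[w]) @ (
            delta_sh(np.array([0.0, 0.0, 1.0]), 8) * resp.convolution_factors(8)
        )
        full = np.concatenate([[1.0], sig_w])
        f = pt.fit_csd(full, scheme61, resp)
        dirs, amps = pt.find_fod_peaks(f)
        assert len(dirs) == 1
        assert abs(dirs[0] @ [0, 0, 1.0]) > np.cos(np.radians(2.0))

    def test_orthogonal_crossing_two_peaks_within_5_deg(self, scheme61):
        resp = pt.tensor_response(1200.0)
        w = scheme61.b_weighted
        sig, u1, u2 = two_tensor_signal(scheme61.directions[w], 1200.0, 90.0)
        fitter = CSDFitter(scheme61, resp)
        dirs, _ = pt.find_fod_peaks(fitter.fit(sig))
        assert len(dirs) == 2
        for u in (u1, u2):
            assert np.degrees(np.arccos(np.abs(dirs @ u).max())) < 5.0

    def test_30_degree_crossing_resolved_on_dense_scheme(self):
        gt = pt.make_gradient_scheme(300, 3000.0, seed=7)
        resp = pt.tensor_response(3000.0)
        fitter = CSDFitter(gt, resp)
        sig, u1, u2 = two_tensor_signal(gt.directions[gt.b_weighted], 3000.0, 30.0)
        dirs, _ = pt.find_fod_peaks(fitter.fit(sig))
        assert len(dirs) == 2

    def test_zero_power_response_rejected(self, scheme61):
        bad = pt.ResponseFunction(
            zonal=np.array([1.0, 0.1, 0.01, 1e-3, 0.0]), lmax=8
        )
        with pytest.raises(ValueError, match="no power at order 8"):
            CSDFitter(scheme61, bad, lmax=8)

    def test_reconvolution_residual_noise_free_single_fibre(self, scheme61):
        resp = pt.tensor_response(1200.0)
        fitter = CSDFitter(scheme61, resp)
        d = scheme61.directions[scheme61.b_weighted]
        sig = np.exp(-1200.0 * (3e-4 + 1.4e-3 * d[:, 2] ** 2))
        f = fitter.fit(sig)
        assert np.abs(fitter.predict(f) - sig).max() < 1e-3

    def test_negative_lobes_bounded_and_clipped_downstream(self, scheme61):
        """The soft constraint keeps residual negativity bounded (the
        band-limited FOD cannot be exactly non-negative at full angular
        resolution); samplers clip at zero."""
        resp = pt.tensor_response(1200.0)
        fitter = CSDFitter(scheme61, resp)
        d = scheme61.directions[scheme61.b_weighted]
        sig = np.exp(-1200.0 * (3e-4 + 1.4e-3 * d[:, 2] ** 2))
        amp = fitter.b_con @ fitter.fit(sig)
        assert amp.min() >= -0.2 * amp.max()

    def test_rotation_equivariance_of_peaks(self):
        """Fitting the signal of a rotated crossing yields the rotated
        peaks (noise-free, within 2 degrees)."""
        gt = pt.make_gradient_scheme(120, 2000.0, seed=5)
        resp = pt.tensor_response(2000.0)
        fitter = CSDFitter(gt, resp)
        d = gt.directions[gt.b_weighted]
        rot = np.array([[0.0, -1.0, 0], [1.0, 0, 0], [0, 0, 1.0]]) @ np.array(
            [[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]]
        )
        sig, u1, u2 = two_tensor_signal(d, 2000.0, 60.0)
        dl = 1.4e-3
        sig_rot = 0.5 * np.exp(
            -2000.0 * (3e-4 + dl * (d @ (rot @ u1)) ** 2)
        ) + 0.5 * np.exp(-2000.0 * (3e-4 + dl * (d @ (rot @ u2)) ** 2))
        p1, _ = pt.find_fod_peaks(fitter.fit(sig))
        p2, _ = pt.find_fod_peaks(fitter.fit(sig_rot))
        assert len(p1) == len(p2) == 2
        for u in p1:
            ang = np.degrees(np.arccos(np.abs(p2 @ (rot @ u)).max()))
            assert ang < 2.0


class TestFODField:
    def test_in_bundle_peaks_follow_tube_tangent(
        self, straight_fod, straight_truth
    ):
        inside = straight_truth.fibre_mask()
        idx = np.argwhere(inside)[::7]
        for i, j, k in idx:
            dirs, _ = pt.find_fod_peaks(straight_fod.coefficients[i, j, k])
            assert len(dirs) >= 1
            ang = np.degrees(np.arccos(abs(dirs[0] @ [0, 0, 1.0])))
            assert ang < 5.0

    def test_background_amplitude_below_tracking_threshold(self, scheme61):
        """Isotropic voxels deconvolve to a flat low FOD: peak amplitude
        under the tracking threshold in >=99% of them (noise-free)."""
        empty = pt.PhantomTruth(shape=(8, 8, 8), voxel_size=1.0)
        dwi = pt.simulate_dwi(
            empty, scheme61, pt.TissueModel(snr=float("inf")), mask_dilation=-1
        )
        fod = pt.fit_fod_field(dwi, pt.tensor_response(1200.0))
        B = sh_basis(8, sphere_points(724))
        amps = fod.coefficients[fod.mask] @ B.T
        frac_low = np.mean(amps.max(axis=1) < pt.TrackingParams().fod_amplitude_threshold)
        assert frac_low >= 0.99

    def test_field_fit_deterministic(self, straight_dwi, straight_response):
        f1 = pt.fit_fod_field(straight_dwi, straight_response)
        f2 = pt.fit_fod_field(straight_dwi, straight_response)
        assert np.array_equal(f1.coefficients, f2.coefficients)


class TestPeaks:
    def test_delta_gives_one_peak_on_axis(self):
        c = delta_sh(np.array([0.0, 0.0, 1.0]), 8)
        dirs, amps = pt.find_fod_peaks(c)
        assert len(dirs) == 1
        assert abs(dirs[0] @ [0, 0, 1.0]) > np.cos(np.radians(1.0))

    def test_peak_set_respects_xy_symmetry(self):
        c = delta_sh(np.array([1.0, 0.0, 0.0]), 8) + delta_sh(
            np.array([0.0, 1.0, 0.0]), 8
        )
        dirs, _ = pt.find_fod_peaks(c)
        assert len(dirs) == 2
        swapped = dirs[:, [1, 0, 2]]
        for s in swapped:
            assert np.abs(dirs @ s).max() > np.cos(np.radians(1.0))

    def test_orthogonal_crossing_exactly_two_peaks(self):
        c = delta_sh(np.array([0.0, 0.0, 1.0]), 8) + delta_sh(
            np.array([1.0, 0.0, 0.0]), 8
        )
        dirs, _ = pt.find_fod_peaks(c, rel_threshold=0.5)
        assert len(dirs) == 2

    def test_zero_coefficients_give_no_peaks(self):
        dirs, amps = pt.find_fod_peaks(np.zeros(45))
        assert len(dirs) == 0 and len(amps) == 0


def test_minimal_resolvable_angle_at_most_30_degrees():
    """5-degree sweep on the dense noise-free scheme: the smallest crossing
    separated into two correct peaks is at most 30 degrees at lmax = 8."""
    smallest, _ = angular_resolution_sweep(
        angles_deg=range(45, 15, -5), scheme_seed=11
    )
    assert smallest <= 30.0
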