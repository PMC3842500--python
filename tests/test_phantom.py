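import copy

import numpy as np
import pytest

import pictract as pt
from pictract.phantom import GradientTable


class TestGradientScheme:
    def test_emulated_acquisition_counts(self, scheme61):
        assert len(scheme61) == 62
        assert int((scheme61.bvalues == 1200.0).sum()) == 61
        assert int((scheme61.bvalues == 0).sum()) == 1

    def test_small_scheme_unit_norms(self):
        gt = pt.make_gradient_scheme(6, 1000.0, seed=0)
        assert len(gt) == 7
        norms = np.linalg.norm(gt.directions[gt.b_weighted], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError, match="insufficient directions"):
            pt.make_gradient_scheme(5, 1000.0, seed=0)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            GradientTable(np.zeros((2, 3)), np.array([0.0]))
        with pytest.raises(ValueError, match="unit norm"):
            GradientTable(
                np.array([[0.0, 0, 0], [0, 0, 0.9]]), np.array([0.0, 1000.0])
            )
        with pytest.raises(ValueError, match="b=0"):
            GradientTable(np.array([[0.0, 0, 1]]), np.array([1000.0]))


class TestBundlePhantoms:
    def test_straight_preset_orientation_and_fraction(self):
        truth = pt.make_bundle_phantom("straight")
        orient, frac, n_pop = truth.populations()
        inside = truth.fibre_mask()
        assert inside.any()
        assert np.all(n_pop[inside] == 1)
        assert np.allclose(orient[inside][:, 0, :], [0.0, 0.0, 1.0])
        assert np.allclose(frac[inside][:, 0], 1.0)

    def test_crossing_overlap_has_two_equal_populations(self):
        truth = pt.make_bundle_phantom("crossing", crossing_angle_deg=90.0)
        _, frac, n_pop = truth.populations()
        overlap = n_pop == 2
        assert overlap.any()
        fr = frac[overlap]
        assert np.allclose(fr[fr > 0], 0.5)

    def test_two_arcs_connections_and_disjoint_tubes(self):
        """Exhaustive voxel-set intersection: the two crescents share no
        voxel, and exactly their two endpoint pairs are declared connected."""
        truth = pt.make_bundle_phantom("two_arcs")
        assert len(truth.truth_connections) == 2
        inner = truth.bundles["inner"].mask
        outer = truth.bundles["outer"].mask
        assert not np.any(inner & outer)
        assert truth.truth_connections == {
            ("inner_A", "inner_B"),
            ("outer_A", "outer_B"),
        }

    def test_out_of_bounds_geometry_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            pt.make_bundle_phantom("straight", shape=(8, 8, 8), tube_radius=6.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            pt.make_bundle_phantom("spiral")


class TestSignalSimulation:
    def test_b0_equals_S0_where_fraction_one(self, straight_truth, scheme61):
        dwi = pt.simulate_dwi(
            straight_truth, scheme61, pt.TissueModel(S0=100.0, snr=float("inf"))
        )
        b0 = dwi.signal[..., ~scheme61.b_weighted][straight_truth.fibre_mask()]
        assert np.allclose(b0, 100.0)

    def test_gradient_along_fibre_attenuates_by_lambda_parallel(self):
        truth = pt.make_bundle_phantom("straight", shape=(12, 12, 24), tube_radius=1.5)
        gt = GradientTable(
            np.array([[0.0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]]),
            np.array([0.0, 1200.0, 1200.0]),
        )
        model = pt.TissueModel(S0=100.0, snr=float("inf"), lambda_perp=3e-4)
        dwi = pt.simulate_dwi(truth, gt, model)
        inside = truth.fibre_mask()
        s_par = dwi.signal[..., 1][inside]
        s_perp = dwi.signal[..., 2][inside]
        assert np.allclose(s_par, 100.0 * np.exp(-1200 * model.lambda_parallel))
        # closed form: 100 * exp(-1200 * 3e-4) = 100 * exp(-0.36) ~ 69.77
        assert np.allclose(s_perp, 100.0 * np.exp(-0.36))
        assert abs(s_perp[0] - 69.7676) < 1e-3

    def test_rician_bias_raises_mean_signal(self):
        """Mean of Rician-noised magnitude exceeds the noise-free signal
        (>=10,000 draws at snr = 5)."""
        empty = pt.PhantomTruth(shape=(22, 22, 22), voxel_size=1.0)
        gt = GradientTable(
            np.array([[0.0, 0, 0], [0, 0, 1.0]]), np.array([0.0, 1200.0])
        )
        clean = pt.simulate_dwi(
            empty, gt, pt.TissueModel(snr=float("inf")), mask_dilation=-1
        ).signal
        noisy = pt.simulate_dwi(
            empty, gt, pt.TissueModel(snr=5.0, rng_seed=2), mask_dilation=-1
        ).signal
        assert clean[..., 0].size >= 10_000
        assert noisy[..., 0].mean() > clean[..., 0].mean()
        assert noisy[..., 1].mean() > clean[..., 1].mean()

    def test_signal_invariant_under_joint_rotation(self, scheme61):
        """Rotating all fibre orientations and all gradient directions by
        the same 90-degree rotation leaves the noise-free signal unchanged."""
        truth = pt.make_bundle_phantom("straight", shape=(14, 14, 14), tube_radius=1.5)
        rot = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        truth_rot = copy.deepcopy(truth)
        for b in truth_rot.bundles.values():
            b.orientations = b.orientations @ rot.T
        gt_rot = GradientTable(scheme61.directions @ rot.T, scheme61.bvalues)
        model = pt.TissueModel(snr=float("inf"))
        s1 = pt.simulate_dwi(truth, scheme61, model).signal
        s2 = pt.simulate_dwi(truth_rot, gt_rot, model).signal
        assert np.abs(s1 - s2).max() < 1e-10

    def test_noise_reproducible_given_seed(self, straight_truth, scheme61):
        m = pt.TissueModel(snr=20.0, rng_seed=9)
        s1 = pt.simulate_dwi(straight_truth, scheme61, m).signal
        s2 = pt.simulate_dwi(straight_truth, scheme61, m).signal
        assert np.array_equal(s1, s2)


class TestCohort:
    @pytest.fixture(scope="class")
    def arcs(self):
        return pt.make_bundle_phantom(
            "two_arcs", shape=(30, 30, 30), tube_radius=1.5
        )

    def test_all_present_cohort(self, arcs):
        gt = pt.make_gradient_scheme(8, 1200.0, seed=0)
        vols, truths = pt.make_cohort(
            arcs, 13, None, pt.TissueModel(snr=30.0), seed=4, gradients=gt
        )
        assert len(vols) == 13
        assert all(len(t.truth_connections) == 2 for t in truths)

    def test_absent_bundles_leave_isotropic_signal(self, arcs):
        gt = pt.make_gradient_scheme(8, 1200.0, seed=0)
        absent = {c: [False] for c in arcs.truth_connections}
        vols, truths = pt.make_cohort(
            arcs, 1, absent, pt.TissueModel(snr=float("inf")), seed=4, gradients=gt
        )
        sig = vols[0].signal[..., gt.b_weighted]
        # no anisotropic voxels: every weighted volume is spatially constant
        assert np.allclose(sig, sig[0, 0, 0, :][None, None, None, :])
        assert truths[0].truth_connections == set()

    def test_designed_presence_count(self, arcs):
        gt = pt.make_gradient_scheme(8, 1200.0, seed=0)
        conn_a = ("inner_A", "inner_B")
        presence = {
            conn_a: [True] * 9 + [False] * 4,
            ("outer_A", "outer_B"): [True] * 13,
        }
        _, truths = pt.make_cohort(
            arcs, 13, presence, pt.TissueModel(snr=30.0), seed=4, gradients=gt
        )
        n_with_a = sum(conn_a in t.truth_connections for t in truths)
        assert n_with_a == 9

    def test_cohort_bit_reproducible(self, arcs):
        gt = pt.make_gradient_scheme(8, 1200.0, seed=0)
        v1, _ = pt.make_cohort(arcs, 3, None, pt.TissueModel(snr=30.0), seed=4,
                               gradients=gt)
        v2, _ = pt.make_cohort(arcs, 3, None, pt.TissueModel(snr=30.0), seed=4,
                               gradients=gt)
        assert all(np.array_equal(a.signal, b.signal) for a, b in zip(v1, v2))

    def test_bad_inputs(self, arcs):
        with pytest.raises(ValueError):
            pt.make_cohort(arcs, 0, None, pt.TissueModel(), seed=1)
        with pytest.raises(ValueError, match="presence"):
            pt.make_cohort(
                arcs, 2, {("inner_A", "inner_B"): [True, True]},
                pt.TissueModel(), seed=1,
            )


class TestLabelVolume:
    def test_two_arcs_has_four_endpoint_labels(self):
        truth = pt.make_bundle_phantom("two_arcs")
        lv = pt.make_label_volume(truth)
        assert len(lv.label_ids) == 4
        assert sorted(lv.names.values()) == [
            "inner_A", "inner_B", "outer_A", "outer_B",
        ]

    def test_straight_has_two_labels(self):
        truth = pt.make_bundle_phantom("straight")
        lv = pt.make_label_volume(truth)
        assert len(lv.label_ids) == 2

    def test_labels_disjoint_by_construction(self):
        # a single integer volume cannot overlap, but every endpoint region
        # must still be non-empty after first-come assignment
        truth = pt.make_bundle_phantom("crossing", crossing_angle_deg=60.0)
        lv = pt.make_label_volume(truth)
        for lab in lv.label_ids:
            assert int((lv.labels == lab).sum()) > 0

    def test_distractors_avoid_bundles_and_endpoints(self):
        truth = pt.make_bundle_phantom("two_arcs")
        lv = pt.make_label_volume(truth, n_distractors=12)
        assert len(lv.label_ids) == 16
        fibre = truth.fibre_mask()
        for lab, name in lv.names.items():
            if name.startswith("background_"):
                assert not np.any((lv.labels == lab) & fibre)
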