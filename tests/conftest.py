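import numpy as np
import pytest

import pictract as pt


@pytest.fixture(scope="session")
def scheme61():
    """61-direction b = 1200 scheme plus one b0 (the emulated acquisition)."""
    return pt.make_gradient_scheme(61, 1200.0, seed=1)


@pytest.fixture(scope="session")
def straight_truth():
    return pt.make_bundle_phantom("straight", shape=(16, 16, 32), tube_radius=2.0)


@pytest.fixture(scope="session")
def straight_dwi(straight_truth, scheme61):
    return pt.simulate_dwi(
        straight_truth, scheme61, pt.TissueModel(snr=float("inf"))
    )


@pytest.fixture(scope="session")
def straight_response(straight_dwi, straight_truth):
    return pt.estimate_response(
        straight_dwi,
        straight_truth.single_fibre_mask(),
        np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture(scope="session")
def straight_fod(straight_dwi, straight_response):
    return pt.fit_fod_field(straight_dwi, straight_response)


@pytest.fixture(scope="session")
def straight_amp(straight_fod):
    return pt.AmplitudeField(straight_fod)


@pytest.fixture(scope="session")
def uniform_z_amp():
    """Spatially uniform delta-z FOD field on an effectively unbounded grid.

    1030 voxels of 1 mm along z fit a 500 mm path from the central seed in
    either direction; 4 mm lateral voxels absorb the sampler's transverse
    drift.  With ~2 steps per 1 mm z-voxel and every admissible draw inside
    the fitted FOD's ~23-degree main lobe, the 180-degree per-voxel
    curvature rule can never trigger — the path limit is the only live
    stopping rule.
    """
    from pictract.csd import CSDFitter, FODField

    # spatially uniform copy of the CSD-fitted single-fibre FOD along z:
    # its amplitude exceeds the 0.2 sampling floor only within ~23 degrees
    # of the axis, so per-voxel turning can never reach 180 degrees
    gt = pt.make_gradient_scheme(61, 1200.0, seed=1)
    fitter = CSDFitter(gt, pt.tensor_response(1200.0))
    d = gt.directions[gt.b_weighted]
    fod_coeffs = fitter.fit(np.exp(-1200.0 * (3e-4 + 1.4e-3 * d[:, 2] ** 2)))
    shape = (8, 8, 1030)
    coeffs = np.broadcast_to(fod_coeffs, shape + (45,)).copy()
    affine = np.diag([4.0, 4.0, 1.0, 1.0])
    fod = FODField(
        coefficients=coeffs,
        lmax=8,
        mask=np.ones(shape, dtype=bool),
        affine=affine,
    )
    return pt.AmplitudeField(fod)


@pytest.fixture(scope="session")
def uniform_z_centre(uniform_z_amp):
    """Centre seed voxel of the unbounded field, as voxel index."""
    return np.array([4, 4, 515])
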