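import numpy as np
import pytest

from flimp.simulate import CameraModel, EmitterPairTruth, render_spot_stack


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture()
def pair_truth():
    """A well-separated two-emitter complex with clean bleach structure."""
    return EmitterPairTruth(
        positions_nm=np.array([[1000.0, 700.0], [400.0, 700.0]]),
        photons_per_frame=5000.0,
        bleach_frames=(12, 25),
        psf_fwhm_nm=300.0,
    )


def make_close_pair(separation_nm, rng, photons=5000.0,
                    bleach=(20, 40), center=(700.0, 700.0)):
    """A complex at the given separation with random orientation."""
    theta = rng.uniform(0, 2 * np.pi)
    half = 0.5 * separation_nm * np.array([np.cos(theta), np.sin(theta)])
    c = np.asarray(center)
    return EmitterPairTruth(
        positions_nm=np.array([c + half, c - half]),
        photons_per_frame=photons,
        bleach_frames=bleach,
        psf_fwhm_nm=270.0,
    )


@pytest.fixture()
def noiseless_stack(pair_truth, camera):
    return render_spot_stack(pair_truth, camera, seed=0, noise=False)
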