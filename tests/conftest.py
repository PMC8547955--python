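import numpy as np
import pytest

from folliquant import afm, synthetic


@pytest.fixture(scope="session")
def probe():
    return afm.ProbeModel()


@pytest.fixture(scope="session")
def wt_sample():
    """Two-layer sample at the wild-type cohort averages: 24.2 kPa
    basement membrane over 10.1 kPa nurse cells."""
    return synthetic.TwoLayerSampleModel(24.2, 10.1)


@pytest.fixture(scope="session")
def uniform_sample():
    """Single-layer 10 kPa sample (shallow == deep)."""
    return synthetic.TwoLayerSampleModel(10.0, 10.0)


@pytest.fixture(scope="session")
def noiseless_acq():
    return synthetic.AcquisitionParams(force_noise_sd_nn=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_wt_curve(wt_sample, noiseless_acq):
    curve, truth = synthetic.simulate_force_curve(wt_sample, acq=noiseless_acq)
    return curve, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    params = synthetic.ImageSceneParams(seed=0, photons_per_au=None)
    return synthetic.simulate_follicle_image(params)


@pytest.fixture(scope="session")
def default_scene():
    params = synthetic.ImageSceneParams(seed=0)
    return synthetic.simulate_follicle_image(params)


#: three horizontal lines crossing the first default membrane (col 140)
MEMBRANE_LINES = [((60, 120), (60, 160)), ((128, 120), (128, 160)), ((200, 120), (200, 160))]

#: translation that places the cluster shape into plain cytoplasm
CYTOPLASM_OFFSET = (100, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
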