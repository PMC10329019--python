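import numpy as np
import pytest

from memsta.simulate import DatasetSpec, PhantomSpec, build_phantom, noise_sigma_for_snr

BOX = 48
PIXEL = 5.0


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return build_phantom(phantom_spec, BOX, PIXEL)


@pytest.fixture(scope="session")
def snr05_sigma(phantom_spec):
    """Noise sigma (fraction of phantom peak) giving box SNR 0.5."""
    return noise_sigma_for_snr(phantom_spec, DatasetSpec(), 0.5, BOX, PIXEL)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # execution order
    return np.random.default_rng(1234)
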