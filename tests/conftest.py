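import numpy as np
import pytest

from flimpipe.decay import LaguerreDeconvolver
from flimpipe.instrument import InstrumentModel, generate_irf


@pytest.fixture(scope="session")
def model():
    return InstrumentModel()


@pytest.fixture(scope="session")
def clean_model():
    """No DC background; convenient for closed-form waveform checks."""
    return InstrumentModel(background_level=0.0)


@pytest.fixture(scope="session")
def small_frame_model():
    """Small frames keep image-heavy tests fast."""
    return InstrumentModel(frame_size=(320, 180))


@pytest.fixture(scope="session")
def irf(model):
    return generate_irf(model)


@pytest.fixture(scope="session")
def deconvolver(model, irf):
    return LaguerreDeconvolver(irf, model.sampling_interval)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
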