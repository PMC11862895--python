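import numpy as np
import pytest

from chiromito import bioacoustics as ba
from chiromito import mito_io
from chiromito import synth_genome as sg


@pytest.fixture(scope="session")
def bcaspica():
    """The bundled published feature annotation (sequence-free)."""
    return mito_io.load_bcaspica_features()


@pytest.fixture(scope="session")
def synth():
    """One deterministic synthetic genome built from the default template."""
    return sg.generate_mitogenome(sg.default_spec(seed=11))


@pytest.fixture(scope="session")
def clean_train():
    """Noise-free 3-pulse FM train with its planted truth."""
    rec, truth = ba.gen_fm_call(
        33.15, 29.82, 2.43, 246.57, 3, snr_db=np.inf, sweep="linear", seed=5
    )
    return rec, truth
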