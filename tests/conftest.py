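import numpy as np
import pytest

from dporkin.synth import NoiseModel, make_reference_set


@pytest.fixture(scope="session")
def clean_noise():
    """Noise model with every artefact switched off (exact forward model)."""
    return NoiseModel(absorbance_sd=0.0, baseline_offset=0.0,
                      baseline_drift=0.0, scatter_coeff=0.0)


@pytest.fixture(scope="session")
def refs():
    """Band-anchored reference set on the default 600-700 nm, 1 nm grid."""
    refset, _ = make_reference_set()
    return refset


@pytest.fixture(scope="session")
def raw_references():
    refset, raw = make_reference_set()
    return raw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
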