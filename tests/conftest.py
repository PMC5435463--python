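import pytest

from t4circuit import synthetic as synth


@pytest.fixture(scope="session")
def lattice7():
    return synth.make_lattice(1)


@pytest.fixture(scope="session")
def default_dataset(lattice7):
    """One 7-column synthetic connectome at the default study conditions."""
    return synth.make_circuit(synth.default_template(), lattice7, seed=7)
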