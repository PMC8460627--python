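import pytest

from loopdyn import SyntheticSpec, make_toy_complex


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def toy(default_spec):
    """Closed-conformation toy tetramer with ground truth (session-wide)."""
    return make_toy_complex(default_spec)


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def tiny_spec():
    """Single short chain, no waters: cheap input for numeric checks."""
    return SyntheticSpec(n_chains=1, residues_per_chain=12, loop_range=(5, 7),
                         hinge_pair=(4, 8), planted_waters=())


@pytest.fixture(scope="session")
def tiny_structure(tiny_spec):
    return make_toy_complex(tiny_spec)[0]
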