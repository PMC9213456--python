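import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from celltab import ToySpec, compile_model, make_toy_model


@pytest.fixture(scope="session")
def default_spec() -> ToySpec:
    return ToySpec()


@pytest.fixture(scope="session")
def toy_set(default_spec):
    return make_toy_model(default_spec)


@pytest.fixture()
def toy_model(toy_set):
    return compile_model(toy_set)


@pytest.fixture(scope="session")
def linear_spec() -> ToySpec:
    """Single unregulated gene, no extras: fully analytic."""
    return ToySpec(n_genes=1, include_ligand_receptor=False,
                   include_death_pair=False, include_cyclin_triple=False)


@pytest.fixture()
def linear_model(linear_spec):
    return compile_model(make_toy_model(linear_spec))
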