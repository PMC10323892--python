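"""Shared fixtures: synthetic complexes and derived objects.

Everything is generated programmatically with fixed seeds so the suite is
fully self-contained and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cyclinterface.interface_analysis import shadow_contact_map
from cyclinterface.sbm_sampler import build_go_potential
from cyclinterface.synthetic_data import SyntheticComplexSpec, make_toy_complex

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_complex():
    """Planted-interface two-chain complex (structure, truth), seed 0."""
    return make_toy_complex(SyntheticComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_structure(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_truth(toy_complex):
    return toy_complex[1]


@pytest.fixture(scope="session")
def toy_contacts(toy_structure):
    return shadow_contact_map(toy_structure)


@pytest.fixture(scope="session")
def toy_potential(toy_structure, toy_contacts):
    return build_go_potential(toy_structure, toy_contacts)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
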