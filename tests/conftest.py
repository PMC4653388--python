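"""Shared fixtures: synthetic systems are generated once per session."""

import numpy as np
import pytest

from cleftdock import DetectionParams, detect_clefts
from cleftdock.fixtures import make_pair, make_shell, make_toy_ligand, make_toy_pocket

# the hollow shell needs a radius window wide enough that midpoint spheres of
# near-antipodal atom pairs can span the cavity interior (~6 Å)
SHELL_PARAMS = DetectionParams(r_min=1.5, r_max=7.0)
POCKET_PARAMS = DetectionParams(r_min=1.5, r_max=4.0)


@pytest.fixture(scope="session")
def pair_structure():
    return make_pair()


@pytest.fixture(scope="session")
def shell_structure():
    return make_shell(radius=8.0, spacing=1.8, vdw=1.8)


@pytest.fixture(scope="session")
def shell_clefts(shell_structure):
    return detect_clefts(shell_structure, SHELL_PARAMS)


@pytest.fixture(scope="session")
def toy_pocket():
    return make_toy_pocket(seed=0)


@pytest.fixture(scope="session")
def pocket_clefts(toy_pocket):
    return detect_clefts(toy_pocket.target, POCKET_PARAMS)


@pytest.fixture(scope="session")
def toy_ligand():
    return make_toy_ligand()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
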