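"""Shared fixtures: expensive reference runs are session-scoped."""

import numpy as np
import pytest

from notchsim import (
    RunConfig,
    default_tissue_graph,
    run_tissue,
    run_two_cell,
)
from notchsim.analysis import fate_proportions


@pytest.fixture(scope="session")
def graph0():
    """The standard 400-cell labeled tissue graph, geometry seed 0."""
    return default_tissue_graph(0)


@pytest.fixture(scope="session")
def wt_tissue(graph0):
    """Wild-type tissue run on the seed-0 geometry."""
    return run_tissue(RunConfig(geometry_seed=0), graph0)


@pytest.fixture(scope="session")
def wt_fates(wt_tissue):
    return fate_proportions(wt_tissue)


@pytest.fixture(scope="session")
def twocell_wt():
    """Two-cell wild-type run (medium cis and trans interaction)."""
    return run_two_cell(RunConfig(preset="table1_twocell"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
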