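"""Shared fixtures: the three-subunit toy complex and its simulated maps.

All maps of the toy complex share the holo grid so that difference/overlap
arithmetic is exact; expensive simulations are session-scoped.
"""

import numpy as np
import pytest

from hybridfit import synth
from hybridfit.grids_io import AtomicModel


@pytest.fixture(scope="session")
def toy_model() -> AtomicModel:
    return synth.toy_complex()


@pytest.fixture(scope="session")
def sim_spec() -> synth.SimulationSpec:
    return synth.SimulationSpec()


@pytest.fixture(scope="session")
def holo_map(toy_model, sim_spec):
    return synth.simulate_map(toy_model, sim_spec)


@pytest.fixture(scope="session")
def subunit_models(toy_model):
    """Single-subunit models keyed by subunit id."""
    return {
        s: synth.make_subcomplex(toy_model, set("ABC") - {s}) for s in "ABC"
    }


@pytest.fixture(scope="session")
def subunit_maps(subunit_models, holo_map, sim_spec):
    """Single-subunit maps on the holo grid, keyed by subunit id."""
    return {
        s: synth.simulate_map(m, sim_spec, origin=holo_map.origin, shape=holo_map.shape)
        for s, m in subunit_models.items()
    }


@pytest.fixture(scope="session")
def pair_maps(toy_model, holo_map, sim_spec):
    """Two-subunit subcomplex maps on the holo grid, keyed by e.g. 'AB'."""
    out = {}
    for pair in ("AB", "BC", "AC"):
        sub = synth.make_subcomplex(toy_model, set("ABC") - set(pair))
        out[pair] = synth.simulate_map(
            sub, sim_spec, origin=holo_map.origin, shape=holo_map.shape
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
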