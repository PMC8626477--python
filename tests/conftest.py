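import numpy as np
import pytest

from corescaffold.model import AtomModel
from corescaffold.synth import (AssemblyScenario, MapSimulationConfig,
                                build_toy_assembly, simulate_map)


def make_model(rows, model_id="test"):
    """Shorthand: rows of (chain, res, resname, atom, element, xyz)."""
    return AtomModel.from_atoms(
        [(c, r, rn, an, el, xyz, 1.0, 20.0) for c, r, rn, an, el, xyz in rows],
        model_id=model_id)


@pytest.fixture(scope="session")
def toy_scenario():
    return AssemblyScenario(seed=11)


@pytest.fixture(scope="session")
def toy_model(toy_scenario):
    return build_toy_assembly(toy_scenario)


@pytest.fixture(scope="session")
def toy_map(toy_model, toy_scenario):
    return simulate_map(toy_model, MapSimulationConfig(seed=11),
                        toy_scenario.weight_by_chain)


@pytest.fixture(scope="session")
def planted_scenario():
    """Six subunits carry the flexible element's density, six lack it."""
    return AssemblyScenario(seed=3, element_weights=[1.0] * 6 + [0.0] * 6)


@pytest.fixture(scope="session")
def planted_map(planted_scenario):
    model = build_toy_assembly(planted_scenario)
    dmap = simulate_map(model, MapSimulationConfig(noise_sd=0.002, seed=7),
                        planted_scenario.weight_by_chain)
    return model, dmap
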