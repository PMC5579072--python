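import numpy as np
import pytest

from stochreach import ReactionNetwork, lna_derive, macroscopic_system
from stochreach.io import load_packaged_model


@pytest.fixture(scope="session")
def gene_network() -> ReactionNetwork:
    """Two-stage gene expression with controlled transcription."""
    return ReactionNetwork(
        species=["m", "p"],
        stoichiometry=[[1, -1, 0, 0], [0, 0, 1, -1]],
        propensities=["k1*mu", "k2*m", "k3*m", "k4*p"],
        parameters={"k1": 100.0, "k2": 5.0, "k3": 100.0, "k4": 1.0},
    )


@pytest.fixture(scope="session")
def gene_system(gene_network):
    return lna_derive(gene_network)


@pytest.fixture(scope="session")
def birth_death() -> ReactionNetwork:
    return ReactionNetwork(
        species=["X"],
        stoichiometry=[[1, -1]],
        propensities=["lam", "gam*X"],
        parameters={"lam": 10.0, "gam": 1.0},
    )


@pytest.fixture(scope="session")
def bistable_model():
    return load_packaged_model("bistable")


@pytest.fixture(scope="session")
def bistable_mean_system(bistable_model):
    return bistable_model.system()


@pytest.fixture(scope="session")
def bistable_lna_system(bistable_model):
    return lna_derive(bistable_model.network())


@pytest.fixture(scope="session")
def cascade_models():
    return {
        name: load_packaged_model(name)
        for name in ("cascade_i", "cascade_ii", "cascade_iii")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170823)
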