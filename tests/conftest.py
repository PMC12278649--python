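import numpy as np
import pytest

from pairview.data import RunConfig
from pairview.fixtures import (FixtureSpec, gen_drugs, gen_expression,
                               gen_networks, gen_triplets)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def drug_fixture(fixture_spec):
    return gen_drugs(fixture_spec)


@pytest.fixture(scope="session")
def network_fixture(fixture_spec):
    return gen_networks(fixture_spec)


@pytest.fixture(scope="session")
def expression_fixture(fixture_spec):
    return gen_expression(fixture_spec)


@pytest.fixture(scope="session")
def triplet_fixture(fixture_spec, drug_fixture, expression_fixture):
    return gen_triplets(fixture_spec, drug_fixture, expression_fixture)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def tiny_config(**overrides) -> RunConfig:
    """Small, fast model configuration used across the unit tests."""
    base = dict(hidden_dim=16, smiles_dim=16, smiles_layers=1, smiles_heads=1,
                graph_dim=16, graph_layers=1, gene_dim=8, ontology_dim=4,
                top_k=4, batch_size=8, steps=10, warmup_steps=2,
                learning_rate=1e-3, seed=5)
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture()
def small_config():
    return tiny_config()


@pytest.fixture(scope="session")
def small_model(fixture_spec, drug_fixture, network_fixture, expression_fixture):
    """A session-scoped untrained model over the synthetic fixture."""
    from pairview.model import DrugCombinationModel

    cfg = tiny_config()
    return DrugCombinationModel(
        drug_fixture.records, cfg, network_fixture.ppi,
        ontology=network_fixture.ontology, expression=expression_fixture,
        task="synergy")
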