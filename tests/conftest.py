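import pytest
from hypothesis import settings

from fluxscreen import fixtures
from fluxscreen.model import Metabolite, MetabolicModel, Reaction

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def chain_model():
    """Linear pathway, uptake bound 10; FBA optimum 10."""
    return fixtures.make_chain(1, 10.0)


@pytest.fixture
def branched_model():
    """Product branch yield 1 gated by gP; wasteful branch yield 0.5 ungated."""
    return fixtures.make_branched(10.0, 1.0, 0.5, gene_gating=True)


@pytest.fixture
def branched_isozyme_model():
    """Product branch gated by the isozyme rule 'gP or gP2'."""
    return fixtures.make_branched(10.0, 1.0, 0.5, gene_gating=True, isozyme=True)


@pytest.fixture
def envelope_model():
    """Waste branch makes no product: 1 unit of waste displaces 1 unit of
    substrate from the product branch."""
    return fixtures.make_branched(10.0, 1.0, 0.0, gene_gating=False)


@pytest.fixture
def diamond_model():
    return fixtures.make_diamond(10.0)


@pytest.fixture
def hand_chain():
    """Hand-built 2-metabolite chain (r1: ->A; r2: A->B; r3: B->), objective
    on export; independent of the fixtures module."""
    return MetabolicModel(
        model_id="hand_chain",
        metabolites=[Metabolite(id="A"), Metabolite(id="B")],
        reactions=[
            Reaction(id="r1", stoichiometry={"A": 1.0}, upper_bound=10.0),
            Reaction(id="r2", stoichiometry={"A": -1.0, "B": 1.0}),
            Reaction(id="r3", stoichiometry={"B": -1.0},
                     objective_coefficient=1.0),
        ],
    )


@pytest.fixture
def all_named_fixtures(chain_model, branched_model, branched_isozyme_model,
                       envelope_model, diamond_model):
    return {
        "chain": chain_model,
        "branched": branched_model,
        "branched_isozyme": branched_isozyme_model,
        "envelope": envelope_model,
        "diamond": diamond_model,
    }
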