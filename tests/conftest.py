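import pytest

from ovoflow.model import MetabolicModel, Metabolite, Reaction


def make_chain() -> MetabolicModel:
    """uptake -> A -> B -> export; uptake capped at 10."""
    mets = [Metabolite("A_c"), Metabolite("B_c")]
    rxns = [
        Reaction("EX_A", {"A_c": -1}, -10, 0),
        Reaction("AB", {"A_c": -1, "B_c": 1}, 0, 1000),
        Reaction("EX_B", {"B_c": -1}, 0, 1000),
    ]
    return MetabolicModel(mets, rxns, id="chain")


def make_diamond() -> MetabolicModel:
    """Two parallel A->B routes between an uptake and an export."""
    mets = [Metabolite("A_c"), Metabolite("B_c")]
    rxns = [
        Reaction("EX_A", {"A_c": -1}, -10, 0),
        Reaction("AB1", {"A_c": -1, "B_c": 1}, 0, 1000),
        Reaction("AB2", {"A_c": -1, "B_c": 1}, 0, 1000),
        Reaction("EX_B", {"B_c": -1}, 0, 1000),
    ]
    return MetabolicModel(mets, rxns, id="diamond")


@pytest.fixture
def chain_model() -> MetabolicModel:
    return make_chain()


@pytest.fixture
def diamond_model() -> MetabolicModel:
    return make_diamond()


@pytest.fixture(scope="session")
def toy_models():
    from ovoflow.synth import toy_follicle_model

    return toy_follicle_model()
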