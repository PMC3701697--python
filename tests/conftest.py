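import networkx as nx
import pytest

from mzactivity.fixtures import generate_toy_model, simulate_feature_table
from mzactivity.model_io import MetabolicModel, Metabolite, Pathway, Reaction


@pytest.fixture
def two_triangle_graph():
    """Two triangles {a,b,c} and {d,e,f} bridged by the edge c-d (E = 7)."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )
    return g


@pytest.fixture
def toy_model():
    """Three metabolites, one reaction A -> B + C, one 2-member pathway."""
    mets = {
        "A": Metabolite("A", "alanine", 89.04768),
        "B": Metabolite("B", "pyruvate", 88.01604),
        "C": Metabolite("C", "massless"),  # unmatchable intermediate
    }
    rxns = [Reaction("R1", ("A",), ("B", "C"), ("2.6.1.2",))]
    pws = [Pathway("P1", "toy pathway", frozenset({"A", "B"}))]
    return MetabolicModel(mets, rxns, pws, frozenset())


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic experiment: 4 planted blocks of 6, one active."""
    model, skeleton = generate_toy_model(seed=7)
    L_ref, L_sig, truth = simulate_feature_table(model, skeleton, seed=7)
    return model, L_ref, L_sig, truth
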