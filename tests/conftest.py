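import pytest

from causenet.model import CausalEdge, CauseEffectModel, Entity, Function, Namespace, Relation


def protein(symbol: str, species: str = "human", **kw) -> Entity:
    ns = Namespace.HGNC if species == "human" else Namespace.MGI
    return Entity(Function.PROTEIN, ns, symbol, **kw)


def bioprocess(name: str) -> Entity:
    return Entity(Function.BIOPROCESS, Namespace.GOBP, name)


def cell(name: str) -> Entity:
    return Entity(Function.CELL_POPULATION, Namespace.MESH, name)


def chemical(name: str) -> Entity:
    return Entity(Function.CHEMICAL, Namespace.CHEBI, name)


def edge(subject, relation, obj, species="human", **kw) -> CausalEdge:
    return CausalEdge(subject, Relation(relation), obj, species=species, **kw)


def model_from(species, *edges) -> CauseEffectModel:
    m = CauseEffectModel(species=species)
    for e in edges:
        m.add_edge(e)
    return m


@pytest.fixture
def tiny_pair():
    """3-edge human model with a fully concordant / contradictory / absent
    mouse counterpart."""
    human = model_from(
        "human",
        edge(protein("TNF"), "increases", protein("NFKB1")),
        edge(protein("NFKB1"), "increases", protein("PTGS2")),
        edge(protein("IL4"), "decreases", bioprocess("inflammatory response")),
    )
    mouse = model_from(
        "mouse",
        edge(protein("Tnf", "mouse"), "increases", protein("Nfkb1", "mouse"), species="mouse"),
        edge(protein("Nfkb1", "mouse"), "decreases", protein("Ptgs2", "mouse"), species="mouse"),
    )
    return human, mouse
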