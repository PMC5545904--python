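"""Core domain types for species-scoped cause-and-effect models.

A model is a directed multigraph of biological entities (proteins, genes,
chemicals, bioprocesses, cell populations, named complexes) connected by
causal or correlative relations. Each relation carries a polarity:

* ``increases`` / ``directlyIncreases``  -> +1
* ``decreases`` / ``directlyDecreases``  -> -1
* ``association`` / ``causesNoChange``   ->  0

Polarity composes multiplicatively along directed paths and is the basis of
both the cross-species concordance classification and the drug
mode-of-action propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional


class Function(str, Enum):
    """Biological function class of an entity."""

    PROTEIN = "protein"
    GENE = "gene"
    CHEMICAL = "chemical"
    BIOPROCESS = "bioprocess"
    CELL_POPULATION = "cell_population"
    COMPLEX = "complex"


class Namespace(str, Enum):
    HGNC = "HGNC"
    MGI = "MGI"
    CHEBI = "CHEBI"
    GOBP = "GOBP"
    MESH = "MESH"
    OTHER = "OTHER"


#: Namespaces that imply a species for the entity they name.
SPECIES_NAMESPACES = {Namespace.HGNC: "human", Namespace.MGI: "mouse"}

#: Namespaces shared between species (chemicals, processes, cell types).
NEUTRAL_NAMESPACES = frozenset({Namespace.CHEBI, Namespace.GOBP, Namespace.MESH, Namespace.OTHER})


class Relation(str, Enum):
    INCREASES = "increases"
    DIRECTLY_INCREASES = "directlyIncreases"
    DECREASES = "decreases"
    DIRECTLY_DECREASES = "directlyDecreases"
    ASSOCIATION = "association"
    CAUSES_NO_CHANGE = "causesNoChange"


#: Total polarity map over the supported relations.
POLARITY: dict[Relation, int] = {
    Relation.INCREASES: +1,
    Relation.DIRECTLY_INCREASES: +1,
    Relation.DECREASES: -1,
    Relation.DIRECTLY_DECREASES: -1,
    Relation.ASSOCIATION: 0,
    Relation.CAUSES_NO_CHANGE: 0,
}

#: Relation with the opposite polarity, preserving directness.
FLIPPED_RELATION: dict[Relation, Relation] = {
    Relation.INCREASES: Relation.DECREASES,
    Relation.DECREASES: Relation.INCREASES,
    Relation.DIRECTLY_INCREASES: Relation.DIRECTLY_DECREASES,
    Relation.DIRECTLY_DECREASES: Relation.DIRECTLY_INCREASES,
    Relation.ASSOCIATION: Relation.ASSOCIATION,
    Relation.CAUSES_NO_CHANGE: Relation.CAUSES_NO_CHANGE,
}

#: Short dialect codes used in node keys and TSV columns.
FUNCTION_CODE = {
    Function.PROTEIN: "p",
    Function.GENE: "g",
    Function.CHEMICAL: "a",
    Function.BIOPROCESS: "bp",
    Function.CELL_POPULATION: "cell",
    Function.COMPLEX: "complex",
}
CODE_FUNCTION = {v: k for k, v in FUNCTION_CODE.items()}

MODIFIABLE_FUNCTIONS = frozenset({Function.PROTEIN, Function.GENE})


class ModelValidationError(ValueError):
    """Raised when a model or one of its parts violates an invariant."""


@dataclass(frozen=True)
class Entity:
    """A species-scoped node.

    ``modification`` is a comma-joined protein/gene modification tag, e.g.
    ``"Ph"`` or ``"Ph,Thr,1462"``; ``activity`` marks an act() wrapper.
    Both are decorations on the entity, not separate nodes: by default
    matching and propagation collapse them onto the undecorated entity.
    """

    function: Function
    namespace: Namespace
    identifier: str
    modification: Optional[str] = None
    activity: bool = False

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ModelValidationError("entity identifier must be non-empty")
        if self.modification is not None and self.function not in MODIFIABLE_FUNCTIONS:
            raise ModelValidationError(
                f"modification tag only allowed on protein/gene entities, not {self.function.value}"
            )

    @property
    def species(self) -> Optional[str]:
        """'human' for HGNC, 'mouse' for MGI, None for neutral namespaces."""
        return SPECIES_NAMESPACES.get(self.namespace)

    def key(self, strict: bool = False) -> str:
        """Canonical node key. With ``strict`` the decorations are included."""
        base = f"{FUNCTION_CODE[self.function]}:{self.namespace.value}:{self.identifier}"
        if strict:
            if self.modification:
                base += f"!pmod({self.modification})"
            if self.activity:
                base += "!act"
        return base

    def base(self) -> "Entity":
        """The entity with decorations stripped."""
        if self.modification is None and not self.activity:
            return self
        return replace(self, modification=None, activity=False)


@dataclass(frozen=True)
class Evidence:
    citation: Optional[str] = None
    text: Optional[str] = None
    order: Optional[int] = None  # statement order in the source document


@dataclass(frozen=True)
class CausalEdge:
    """One causal or correlative statement: subject -relation-> object."""

    subject: Entity
    relation: Relation
    object: Entity
    species: str = "human"
    evidence: Optional[Evidence] = None

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ModelValidationError(f"unknown species {self.species!r}")
        for endpoint in (self.subject, self.object):
            if endpoint.species is not None and endpoint.species != self.species:
                raise ModelValidationError(
                    f"{endpoint.key()} carries species {endpoint.species!r} "
                    f"but the edge is tagged {self.species!r}"
                )

    @property
    def polarity(self) -> int:
        return POLARITY[self.relation]

    @property
    def is_directed(self) -> bool:
        """association is symmetric; every other relation is directed."""
        return self.relation is not Relation.ASSOCIATION

    def canonical_triple(self, strict: bool = False) -> tuple[str, str, str]:
        """Identity triple; association edges are oriented lexicographically."""
        s, o = self.subject.key(strict), self.object.key(strict)
        if not self.is_directed and o < s:
            s, o = o, s
        return (s, self.relation.value, o)


@dataclass
class CauseEffectModel:
    """One species' causal graph: an entity set plus an edge multiset.

    The edge list is a multiset — one record per curated statement — so
    ``statement_count`` (number of statements) can exceed the number of
    distinct (subject, relation, object) triples.
    """

    species: str
    entities: set[Entity] = field(default_factory=set)
    edges: list[CausalEdge] = field(default_factory=list)

    @property
    def statement_count(self) -> int:
        return len(self.edges)

    def add_edge(self, edge: CausalEdge) -> None:
        if edge.species != self.species:
            raise ModelValidationError(
                f"edge tagged {edge.species!r} added to a {self.species!r} model"
            )
        self.entities.add(edge.subject)
        self.entities.add(edge.object)
        self.edges.append(edge)

    def add_entity(self, entity: Entity) -> None:
        if entity.species is not None and entity.species != self.species:
            raise ModelValidationError(
                f"{entity.key()} carries species {entity.species!r} "
                f"in a {self.species!r} model"
            )
        self.entities.add(entity)

    def distinct_triples(self, strict: bool = False) -> set[tuple[str, str, str]]:
        return {e.canonical_triple(strict) for e in self.edges}

    def validate(self) -> None:
        for edge in self.edges:
            if edge.subject not in self.entities or edge.object not in self.entities:
                raise ModelValidationError(
                    f"edge endpoint missing from entity set: {edge.canonical_triple()}"
                )
            if edge.species != self.species:
                raise ModelValidationError("edge species differs from model species")
        for entity in self.entities:
            if entity.species is not None and entity.species != self.species:
                raise ModelValidationError(
                    f"{entity.key()} namespace conflicts with model species {self.species!r}"
                )

    def __eq__(self, other: object) -> bool:
        """Statement-order metadata is ignored: two models are equal when they
        have the same species, entities, and multiset of (strict triple,
        citation, evidence text)."""
        if not isinstance(other, CauseEffectModel):
            return NotImplemented

        def sig(m: "CauseEffectModel"):
            return sorted(
                (
                    e.canonical_triple(strict=True),
                    e.evidence.citation if e.evidence else None,
                    e.evidence.text if e.evidence else None,
                )
                for e in m.edges
            )

        return (
            self.species == other.species
            and self.entities == other.entities
            and sig(self) == sig(other)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CauseEffectModel(species={self.species!r}, "
            f"nodes={len(self.entities)}, statements={self.statement_count})"
        )


def entities_from_edges(edges: Iterable[CausalEdge]) -> set[Entity]:
    out: set[Entity] = set()
    for e in edges:
        out.add(e.subject)
        out.add(e.object)
    return out
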