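"""Signed-path drug mode-of-action propagation.

Given a drug with signed target actions (e.g. celecoxib inhibits PTGS2 and
PDPK1, action sign -1 on both), the engine enumerates simple directed paths
(no repeated node) of bounded length from each target through polar edges
and assigns each reached node a net predicted sign: the action sign times
the product of edge polarities along the path. A node reached by both a +1
and a -1 path is flagged as a conflict rather than resolved numerically.
Correlative (zero-polarity) edges carry no sign and are excluded.

Results from the human and mouse models can be compared node-by-node via
orthology to surface where the two species' predicted drug responses agree,
disagree, or exist in only one species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .model import CausalEdge, CauseEffectModel, Entity, Namespace, NEUTRAL_NAMESPACES
from .orthology import OrthologyMap, map_entity_candidates

logger = logging.getLogger(__name__)

CONFLICT = "conflict"
UNREACHED = "unreached"


class PerturbationError(ValueError):
    pass


@dataclass(frozen=True)
class DrugAction:
    """A drug and its signed target actions (+1 activation, -1 inhibition)."""

    drug: str
    targets: tuple[tuple[Entity, int], ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise PerturbationError("drug action needs at least one target")
        for entity, sign in self.targets:
            if sign not in (+1, -1):
                raise PerturbationError(f"target {entity.key()} has non-polar sign {sign}")


@dataclass(frozen=True)
class SignedPath:
    nodes: tuple[str, ...]  # node keys, starting at the drug target
    edge_signs: tuple[int, ...]
    action_sign: int

    @property
    def sign(self) -> int:
        s = self.action_sign
        for e in self.edge_signs:
            s *= e
        return s


@dataclass
class NodeOutcome:
    net_sign: Union[int, str]  # +1 / -1 / "conflict"
    paths: list[SignedPath] = field(default_factory=list)


@dataclass
class PerturbationResult:
    drug: str
    species: str
    max_len: int
    outcomes: dict[str, NodeOutcome] = field(default_factory=dict)
    entities: dict[str, Entity] = field(default_factory=dict)  # node key -> entity
    skipped_targets: list[str] = field(default_factory=list)

    def net_sign(self, node_key: str) -> Union[int, str]:
        if node_key not in self.outcomes:
            return UNREACHED
        return self.outcomes[node_key].net_sign


def _polar_adjacency(model: CauseEffectModel) -> dict[str, list[tuple[str, int]]]:
    """Adjacency over base node keys; parallel polar edges deduplicated to
    their distinct signs; zero-polarity edges dropped."""
    seen: set[tuple[str, str, int]] = set()
    adj: dict[str, list[tuple[str, int]]] = {}
    for edge in model.edges:
        if edge.polarity == 0:
            continue
        s, o = edge.subject.base().key(), edge.object.base().key()
        item = (s, o, edge.polarity)
        if item in seen or s == o:
            continue
        seen.add(item)
        adj.setdefault(s, []).append((o, edge.polarity))
    for key in adj:
        adj[key].sort()
    return adj


def propagate(
    model: CauseEffectModel,
    action: DrugAction,
    max_len: int = 6,
    omap: Optional[OrthologyMap] = None,
) -> PerturbationResult:
    """Enumerate signed simple paths from each drug target.

    Targets are matched to model nodes by their undecorated key; targets
    stated for the other species are translated through the orthology map
    (case-convention fallback by default). Missing targets are skipped with
    a warning; if no target is present in the model this raises.

    The target node itself carries its action sign (the length-0 path).
    ``max_len`` bounds path length in edges. Cycles terminate because paths
    never repeat a node.
    """
    if max_len < 1:
        raise PerturbationError("max_len must be >= 1")
    omap = omap or OrthologyMap()
    adj = _polar_adjacency(model)
    node_keys = {e.base().key() for e in model.entities}
    entities = {e.base().key(): e.base() for e in model.entities}

    result = PerturbationResult(action.drug, model.species, max_len, entities=entities)
    signs_seen: dict[str, set[int]] = {}
    paths_by_node: dict[str, list[SignedPath]] = {}

    resolved: list[tuple[str, int]] = []
    for entity, sign in action.targets:
        candidates = [
            c.base().key()
            for c in map_entity_candidates(entity, omap, model.species)
        ]
        present = [k for k in candidates if k in node_keys]
        if not present:
            logger.warning(
                "%s target %s not present in the %s model; skipped",
                action.drug,
                entity.key(),
                model.species,
            )
            result.skipped_targets.append(entity.key())
            continue
        for key in present:
            resolved.append((key, sign))
    if not resolved:
        raise PerturbationError(
            f"none of {action.drug}'s targets are present in the {model.species} model"
        )

    def record(path: SignedPath) -> None:
        node = path.nodes[-1]
        signs_seen.setdefault(node, set()).add(path.sign)
        paths_by_node.setdefault(node, []).append(path)

    for start, action_sign in resolved:
        record(SignedPath((start,), (), action_sign))

        def dfs(path_nodes: list[str], edge_signs: list[int], visited: set[str]) -> None:
            if len(edge_signs) >= max_len:
                return
            for nbr, sign in adj.get(path_nodes[-1], ()):
                if nbr in visited:
                    continue
                path_nodes.append(nbr)
                edge_signs.append(sign)
                visited.add(nbr)
                record(SignedPath(tuple(path_nodes), tuple(edge_signs), action_sign))
                dfs(path_nodes, edge_signs, visited)
                visited.remove(nbr)
                edge_signs.pop()
                path_nodes.pop()

        dfs([start], [], {start})

    for node in sorted(signs_seen):
        signs = signs_seen[node]
        net: Union[int, str] = CONFLICT if len(signs) > 1 else next(iter(signs))
        result.outcomes[node] = NodeOutcome(net, sorted(paths_by_node[node], key=lambda p: p.nodes))
    return result


AGREE = "agree"
DISAGREE = "disagree"
AGREE_ON_CONFLICT = "agree_on_conflict"
A_ONLY = "a_only"
B_ONLY = "b_only"


def _translate_key(entity: Entity, omap: OrthologyMap, target_species: str) -> Optional[str]:
    candidates = map_entity_candidates(entity.base(), omap, target_species)
    return candidates[0].key() if candidates else None


def compare_perturbation(
    result_a: PerturbationResult,
    result_b: PerturbationResult,
    omap: Optional[OrthologyMap] = None,
) -> dict:
    """Pair downstream nodes across species and bucket the agreement.

    Buckets: agree (same pure sign), agree_on_conflict (both conflicted),
    disagree (both reached but different outcome, including conflict vs pure
    sign), a_only / b_only (reached in one species only). Keys in the output
    are node keys of ``result_a``'s species (b-only nodes keep their own).
    """
    if result_a.species == result_b.species:
        raise PerturbationError("compare_perturbation expects results from different species")
    omap = omap or OrthologyMap()

    buckets: dict[str, list] = {AGREE: [], DISAGREE: [], AGREE_ON_CONFLICT: [], A_ONLY: [], B_ONLY: []}
    matched_b: set[str] = set()
    for a_key in sorted(result_a.outcomes):
        entity = result_a.entities[a_key]
        b_key = _translate_key(entity, omap, result_b.species)
        if b_key is None or b_key not in result_b.outcomes:
            buckets[A_ONLY].append({"node": a_key, "sign": result_a.net_sign(a_key)})
            continue
        matched_b.add(b_key)
        sa, sb = result_a.net_sign(a_key), result_b.net_sign(b_key)
        entry = {"node": a_key, "counterpart": b_key, "a_sign": sa, "b_sign": sb}
        if sa == CONFLICT and sb == CONFLICT:
            buckets[AGREE_ON_CONFLICT].append(entry)
        elif sa == sb:
            buckets[AGREE].append(entry)
        else:
            buckets[DISAGREE].append(entry)
    for b_key in sorted(set(result_b.outcomes) - matched_b):
        buckets[B_ONLY].append({"node": b_key, "sign": result_b.net_sign(b_key)})
    return buckets


def load_drug_action(source: Union[str, Path]) -> DrugAction:
    """Load a drug-action YAML: ``drug: name`` plus ``targets:`` entries of
    ``{entity: "p(HGNC:PTGS2)", sign: -1}``."""
    from .io import parse_term

    doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict) or "drug" not in doc or "targets" not in doc:
        raise PerturbationError("drug YAML needs 'drug' and 'targets' keys")
    targets = tuple(
        (parse_term(t["entity"]), int(t["sign"])) for t in doc["targets"]
    )
    return DrugAction(str(doc["drug"]), targets)
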