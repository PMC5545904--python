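"""Cross-species edge concordance.

Each human edge is classified against the mouse model:

* **consistent** — a mouse edge over the orthology-mapped endpoints, same
  direction, same nonzero polarity (Fig.-3-style black edges);
* **contradictory** — a matching mouse edge with the opposite nonzero
  polarity (red edges);
* **unique_to_human** — no matching mouse edge (blue edges).

Mouse edges with no human counterpart are reported separately as
**unique_to_mouse**. Edges are stratified by level: *molecular* when both
endpoints are protein/gene/chemical/complex, *cellular* when either
endpoint is a bioprocess or a cell population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import CausalEdge, CauseEffectModel, Entity, Function
from .orthology import OrthologyMap, map_entity_candidates

MOLECULAR_FUNCTIONS = frozenset(
    {Function.PROTEIN, Function.GENE, Function.CHEMICAL, Function.COMPLEX}
)

CONSISTENT = "consistent"
CONTRADICTORY = "contradictory"
UNIQUE_TO_HUMAN = "unique_to_human"
UNIQUE_TO_MOUSE = "unique_to_mouse"
CATEGORIES = (CONSISTENT, CONTRADICTORY, UNIQUE_TO_HUMAN)

MOLECULAR = "molecular"
CELLULAR = "cellular"
LEVELS = (MOLECULAR, CELLULAR)


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (so 62.5 -> 63)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratify_level(edge: CausalEdge) -> str:
    """molecular iff both endpoints are protein/gene/chemical/complex."""
    if (
        edge.subject.function in MOLECULAR_FUNCTIONS
        and edge.object.function in MOLECULAR_FUNCTIONS
    ):
        return MOLECULAR
    return CELLULAR


@dataclass(frozen=True)
class ComparisonRecord:
    """Classification of one human edge against the mouse model."""

    human_edge: CausalEdge
    mouse_match: Optional[CausalEdge]
    category: str
    level: str
    nonpolar_match: bool = False
    mixed_evidence: bool = False
    no_orthology: bool = False


@dataclass
class ConcordanceSummary:
    """Per (level x category) counts and integer percentages.

    Percentages use round-half-away-from-zero; within a level the counts sum
    to the level denominator.
    """

    counts: dict = field(default_factory=dict)  # level -> {category: count}
    denominators: dict = field(default_factory=dict)  # level -> int

    @property
    def percentages(self) -> dict:
        out: dict = {}
        for level, cats in self.counts.items():
            denom = self.denominators.get(level, 0)
            out[level] = {
                cat: (round_half_away(100.0 * n / denom) if denom else 0)
                for cat, n in cats.items()
            }
        return out

    def total_counts(self) -> dict:
        out: dict[str, int] = {c: 0 for c in CATEGORIES}
        for cats in self.counts.values():
            for cat, n in cats.items():
                out[cat] = out.get(cat, 0) + n
        return out


class _EdgeIndex:
    """Mouse edges indexed by (subject key, object key); association edges
    are indexed in both orientations."""

    def __init__(self, model: CauseEffectModel, strict: bool):
        self.strict = strict
        self._index: dict[tuple[str, str], list[CausalEdge]] = {}
        for edge in model.edges:
            s = self._node_key(edge.subject)
            o = self._node_key(edge.object)
            self._index.setdefault((s, o), []).append(edge)
            if not edge.is_directed and s != o:
                self._index.setdefault((o, s), []).append(edge)

    def _node_key(self, entity: Entity) -> str:
        return entity.key(strict=self.strict)

    def lookup(self, subject: Entity, obj: Entity, either_direction: bool) -> list[CausalEdge]:
        s, o = self._node_key(subject), self._node_key(obj)
        hits = list(self._index.get((s, o), ()))
        if either_direction and s != o:
            for e in self._index.get((o, s), ()):
                if e not in hits:
                    hits.append(e)
        return hits


def _candidate_edges(
    edge: CausalEdge,
    index: _EdgeIndex,
    omap: OrthologyMap,
    target_species: str,
) -> tuple[Optional[list[CausalEdge]], bool]:
    """(candidates, no_orthology). candidates=None when an endpoint cannot be
    mapped at all (table_only policy with an absent pair)."""
    subj_cands = map_entity_candidates(edge.subject, omap, target_species)
    obj_cands = map_entity_candidates(edge.object, omap, target_species)
    if not subj_cands or not obj_cands:
        return None, True
    hits: list[CausalEdge] = []
    for s in subj_cands:
        for o in obj_cands:
            for cand in index.lookup(s, o, either_direction=not edge.is_directed):
                if cand not in hits:
                    hits.append(cand)
    return hits, False


def classify_edge(
    human_edge: CausalEdge,
    mouse_model: CauseEffectModel,
    omap: OrthologyMap,
    strict: bool = False,
    nonpolar_as_consistent: bool = True,
    _index: Optional[_EdgeIndex] = None,
) -> ComparisonRecord:
    """Classify one human edge against the mouse model.

    Matching ignores pmod/act decorations unless ``strict``. Zero-polarity
    (correlative) mouse support for a polar human edge counts as consistent
    with ``nonpolar_match=True`` by default; set ``nonpolar_as_consistent``
    False to demote it to unique_to_human. When matching evidence carries
    both equal and opposite polarity the record is consistent but flagged
    ``mixed_evidence``.
    """
    index = _index if _index is not None else _EdgeIndex(mouse_model, strict)
    level = stratify_level(human_edge)
    candidates, no_orth = _candidate_edges(human_edge, index, omap, mouse_model.species)
    if candidates is None:
        return ComparisonRecord(human_edge, None, UNIQUE_TO_HUMAN, level, no_orthology=True)

    hp = human_edge.polarity
    if hp != 0:
        equal = [c for c in candidates if c.polarity == hp]
        opposite = [c for c in candidates if c.polarity == -hp]
        zero = [c for c in candidates if c.polarity == 0]
        if equal:
            return ComparisonRecord(
                human_edge, equal[0], CONSISTENT, level, mixed_evidence=bool(opposite)
            )
        if opposite:
            return ComparisonRecord(human_edge, opposite[0], CONTRADICTORY, level)
        if zero:
            if nonpolar_as_consistent:
                return ComparisonRecord(human_edge, zero[0], CONSISTENT, level, nonpolar_match=True)
            return ComparisonRecord(human_edge, zero[0], UNIQUE_TO_HUMAN, level, nonpolar_match=True)
        return ComparisonRecord(human_edge, None, UNIQUE_TO_HUMAN, level)

    # Correlative human edge: any matching mouse edge supports it.
    zero = [c for c in candidates if c.polarity == 0]
    if zero:
        return ComparisonRecord(human_edge, zero[0], CONSISTENT, level)
    if candidates:
        return ComparisonRecord(human_edge, candidates[0], CONSISTENT, level, nonpolar_match=True)
    return ComparisonRecord(human_edge, None, UNIQUE_TO_HUMAN, level)


@dataclass
class ComparisonResult:
    records: list[ComparisonRecord]
    mouse_only: list[ComparisonRecord]  # category unique_to_mouse
    summary: ConcordanceSummary
    mouse_only_counts: dict = field(default_factory=dict)  # level -> count


def _summarize(records: Sequence[ComparisonRecord]) -> ConcordanceSummary:
    counts: dict = {}
    denominators: dict = {}
    for rec in records:
        lvl = counts.setdefault(rec.level, {c: 0 for c in CATEGORIES})
        lvl[rec.category] += 1
        denominators[rec.level] = denominators.get(rec.level, 0) + 1
    return ConcordanceSummary(counts=counts, denominators=denominators)


def compare_models(
    human: CauseEffectModel,
    mouse: CauseEffectModel,
    omap: OrthologyMap,
    scope: Optional[Iterable[CausalEdge]] = None,
    strict: bool = False,
    nonpolar_as_consistent: bool = True,
) -> ComparisonResult:
    """Classify every in-scope human edge; report unmatched mouse edges.

    ``scope`` restricts the human edges considered (e.g. one pathway's edge
    list); it defaults to all distinct human edges. Duplicate statements
    over the same triple are classified once. Mouse edges whose mapped
    endpoints carry no human edge in the same direction (any polarity) are
    returned as unique_to_mouse, in a separate section with its own
    per-level counts.
    """
    human.validate()
    mouse.validate()
    index = _EdgeIndex(mouse, strict)

    if scope is None:
        scope_edges = _distinct_in_order(human.edges, strict)
    else:
        scope_edges = _distinct_in_order(list(scope), strict)

    records = [
        classify_edge(e, mouse, omap, strict, nonpolar_as_consistent, _index=index)
        for e in scope_edges
    ]

    human_index = _EdgeIndex(human, strict)
    mouse_only: list[ComparisonRecord] = []
    for medge in _distinct_in_order(mouse.edges, strict):
        counterparts, no_orth = _candidate_edges(medge, human_index, omap, human.species)
        if counterparts is None or not counterparts:
            mouse_only.append(
                ComparisonRecord(
                    medge, None, UNIQUE_TO_MOUSE, stratify_level(medge), no_orthology=no_orth
                )
            )

    mo_counts: dict[str, int] = {}
    for rec in mouse_only:
        mo_counts[rec.level] = mo_counts.get(rec.level, 0) + 1

    return ComparisonResult(
        records=records,
        mouse_only=mouse_only,
        summary=_summarize(records),
        mouse_only_counts=mo_counts,
    )


def _distinct_in_order(edges: Sequence[CausalEdge], strict: bool) -> list[CausalEdge]:
    seen: set[tuple[str, str, str]] = set()
    out: list[CausalEdge] = []
    for e in edges:
        t = e.canonical_triple(strict)
        if t not in seen:
            seen.add(t)
            out.append(e)
    return out


def records_to_table(result: ComparisonResult):
    """Flatten a ComparisonResult to a pandas DataFrame (one row per record,
    mouse-only section appended)."""
    import pandas as pd

    rows = []
    for rec in list(result.records) + list(result.mouse_only):
        e = rec.human_edge
        rows.append(
            {
                "subject": e.subject.key(True),
                "relation": e.relation.value,
                "object": e.object.key(True),
                "species": e.species,
                "category": rec.category,
                "level": rec.level,
                "match_subject": rec.mouse_match.subject.key(True) if rec.mouse_match else None,
                "match_relation": rec.mouse_match.relation.value if rec.mouse_match else None,
                "match_object": rec.mouse_match.object.key(True) if rec.mouse_match else None,
                "nonpolar_match": rec.nonpolar_match,
                "mixed_evidence": rec.mixed_evidence,
                "no_orthology": rec.no_orthology,
            }
        )
    return pd.DataFrame(rows)
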