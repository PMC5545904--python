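"""Human<->mouse identifier mapping.

Orthology here is symbol-level: a curated table of (human_symbol,
mouse_symbol) pairs, optionally backed by the gene-nomenclature case
convention (human symbols all-caps, mouse symbols capitalized), under which
e.g. NFKB1 <-> Nfkb1. Species-neutral namespaces (CHEBI, GOBP, MESH, OTHER)
map to themselves. One-to-many orthology is allowed; every counterpart is a
candidate during edge matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import Entity, Namespace, NEUTRAL_NAMESPACES

TABLE_ONLY = "table_only"
TABLE_THEN_CASEFOLD = "table_then_casefold"


class OrthologySchemaError(ValueError):
    pass


def _casefold_to(symbol: str, target_species: str) -> str:
    if target_species == "human":
        return symbol.upper()
    return symbol[:1].upper() + symbol[1:].lower()


@dataclass(frozen=True)
class OrthologyMap:
    """Symmetric symbol map with an optional case-convention fallback."""

    pairs: frozenset[tuple[str, str]] = frozenset()
    policy: str = TABLE_THEN_CASEFOLD
    _h2m: dict = field(default_factory=dict, compare=False, repr=False)
    _m2h: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.policy not in (TABLE_ONLY, TABLE_THEN_CASEFOLD):
            raise ValueError(f"unknown orthology policy {self.policy!r}")
        for h, m in sorted(self.pairs):
            if not h or not m:
                raise OrthologySchemaError("empty symbol in orthology pair")
            self._h2m.setdefault(h, []).append(m)
            self._m2h.setdefault(m, []).append(h)

    def map_symbol(self, symbol: str, target_species: str) -> tuple[str, ...]:
        """All candidate counterparts of ``symbol`` in the target species.

        Empty tuple means "no mapping" (only possible under table_only).
        """
        table = self._m2h if target_species == "human" else self._h2m
        if symbol in table:
            return tuple(table[symbol])
        if self.policy == TABLE_THEN_CASEFOLD:
            return (_casefold_to(symbol, target_species),)
        return ()

    def has_one_to_many(self) -> bool:
        return any(len(v) > 1 for v in (*self._h2m.values(), *self._m2h.values()))


_TARGET_NAMESPACE = {"human": Namespace.HGNC, "mouse": Namespace.MGI}


def map_entity_candidates(
    entity: Entity, omap: OrthologyMap, target_species: str
) -> tuple[Entity, ...]:
    """All candidate translations of an entity into the target species.

    Function class, modification and activity decorations are never changed.
    Species-neutral entities map to themselves; an entity already in the
    target species maps to itself.
    """
    if entity.namespace in NEUTRAL_NAMESPACES:
        return (entity,)
    if entity.species == target_species:
        return (entity,)
    symbols = omap.map_symbol(entity.identifier, target_species)
    ns = _TARGET_NAMESPACE[target_species]
    return tuple(replace(entity, namespace=ns, identifier=s) for s in symbols)


def map_entity(entity: Entity, omap: OrthologyMap, target_species: str) -> Optional[Entity]:
    """First candidate translation, or None when no mapping exists."""
    candidates = map_entity_candidates(entity, omap, target_species)
    return candidates[0] if candidates else None


def load_orthology_table(
    source: Union[str, Path, pd.DataFrame], policy: str = TABLE_THEN_CASEFOLD
) -> OrthologyMap:
    """Load an orthology TSV with columns human_symbol, mouse_symbol."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    for col in ("human_symbol", "mouse_symbol"):
        if col not in df.columns:
            raise OrthologySchemaError(f"orthology table missing column {col!r}")
    pairs = set()
    for _, row in df.iterrows():
        h, m = row["human_symbol"], row["mouse_symbol"]
        if pd.isna(h) or pd.isna(m) or not str(h).strip() or not str(m).strip():
            raise OrthologySchemaError("empty cell in orthology table")
        pairs.add((str(h).strip(), str(m).strip()))
    return OrthologyMap(pairs=frozenset(pairs), policy=policy)
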