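"""Over-representation analysis (ORA) against user-supplied gene sets.

A plain hypergeometric upper-tail test per gene set with Benjamini-Hochberg
adjustment across sets. Gene-set collections come in GMT layout (set name,
description, tab-separated members). Results from two species over the same
collection can be partitioned into shared and species-unique significant
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: tuple[tuple[str, frozenset[str]], ...]
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.sets]
        if len(names) != len(set(names)):
            raise EnrichmentError("gene-set names must be unique")
        for name, members in self.sets:
            if not members:
                raise EnrichmentError(f"gene set {name!r} is empty")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.sets)

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(self.sets)


def make_collection(
    sets: dict[str, Iterable[str]], universe: Optional[Iterable[str]] = None
) -> GeneSetCollection:
    return GeneSetCollection(
        sets=tuple((name, frozenset(s.upper() for s in members)) for name, members in sets.items()),
        universe=frozenset(g.upper() for g in universe) if universe is not None else None,
    )


def load_gmt(source: Union[str, Path]) -> GeneSetCollection:
    """Load a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    for raw in Path(source).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = parts
        if name in sets:
            raise EnrichmentError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in genes if g]
    return make_collection(sets)


def ora(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list per set.

    For each set of size K in a universe of size N, with query size n and
    overlap k, p = P(X >= k) for X ~ Hypergeom(N, K, n); q is the
    Benjamini-Hochberg adjustment of p across all sets in the collection.
    The universe defaults to the collection's declared background, else the
    union of all set members. Query genes outside the universe are dropped
    with a warning. Rows are sorted by (p, set name).
    """
    query = {g.upper() for g in query_genes}
    if universe is not None:
        uni = {g.upper() for g in universe}
    elif collection.universe is not None:
        uni = set(collection.universe)
    else:
        uni = set()
        for _, members in collection.sets:
            uni |= members
    if not uni:
        raise EnrichmentError("empty universe")

    outside = query - uni
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= uni

    N, n = len(uni), len(query)
    rows = []
    for name, members in collection.sets:
        inset = members & uni
        K = len(inset)
        k = len(query & inset)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return df


def shared_unique_sets(
    result_human: pd.DataFrame,
    result_mouse: pd.DataFrame,
    q_threshold: float = 0.05,
) -> dict:
    """Partition significant sets into shared / unique_to_human /
    unique_to_mouse by whether q <= threshold in one or both species.

    Both results must come from the same collection (same set names).
    """
    names_h = set(result_human["set_name"])
    names_m = set(result_mouse["set_name"])
    if names_h != names_m:
        raise EnrichmentError("results come from different gene-set collections")
    sig_h = set(result_human.loc[result_human["q_value"] <= q_threshold, "set_name"])
    sig_m = set(result_mouse.loc[result_mouse["q_value"] <= q_threshold, "set_name"])
    return {
        "shared": sorted(sig_h & sig_m),
        "unique_to_human": sorted(sig_h - sig_m),
        "unique_to_mouse": sorted(sig_m - sig_h),
    }
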