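"""Cross-species differential-expression concordance.

Consumes pre-computed per-gene differential-expression call tables (the
layout GEO2R exports: Gene.symbol, logFC, P.Value, optional adj.P.Val) and
classifies each gene into one of six categories by comparing its
significant directions across species:

same_pattern, human_only, mouse_only, inconsistent_within_species,
contradictory_between_species, non_significant.

Precedence (evaluated in order):

1. inconsistent_within_species — any single species shows both a
   significant up and a significant down call for the gene;
2. non_significant — every call in both species is non-significant;
3. human_only / mouse_only — exactly one species has >=1 significant call;
4. same_pattern — both species' significant directions agree;
5. contradictory_between_species — they disagree.

Raw-data reanalysis is out of scope: tables are consumed as published.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .concordance import round_half_away
from .orthology import OrthologyMap, _casefold_to

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"

SAME_PATTERN = "same_pattern"
HUMAN_ONLY = "human_only"
MOUSE_ONLY = "mouse_only"
INCONSISTENT_WITHIN = "inconsistent_within_species"
CONTRADICTORY_BETWEEN = "contradictory_between_species"
NON_SIGNIFICANT = "non_significant"
EXPRESSION_CATEGORIES = (
    SAME_PATTERN,
    HUMAN_ONLY,
    MOUSE_ONLY,
    INCONSISTENT_WITHIN,
    CONTRADICTORY_BETWEEN,
    NON_SIGNIFICANT,
)


class ExpressionSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionCall:
    """One per-gene differential-expression call from one dataset."""

    gene_symbol: str
    species: str
    dataset_accession: str
    log_fold_change: float
    p_value: float
    adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ExpressionSchemaError("gene symbol must be non-empty")
        for name, p in (("p_value", self.p_value), ("adjusted_p", self.adjusted_p)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ExpressionSchemaError(f"{name} outside [0, 1]: {p}")


@dataclass(frozen=True)
class GeneConcordance:
    gene_symbol: str  # human-space symbol
    category: str
    human_calls: tuple[ExpressionCall, ...] = ()
    mouse_calls: tuple[ExpressionCall, ...] = ()


_REQUIRED_COLUMNS = ("Gene.symbol", "logFC", "P.Value")


def normalize_symbol(symbol: str, species: str) -> str:
    return _casefold_to(symbol.strip(), species)


def load_de_table(
    source: Union[str, Path, pd.DataFrame],
    species: str,
    accession: str,
    collapse_probes: bool = True,
) -> list[ExpressionCall]:
    """Load a GEO2R-style differential-expression table.

    Rows with an empty gene symbol are dropped with a warning. Multiple
    probes per gene are collapsed to the best (smallest) unadjusted p-value,
    unless ``collapse_probes`` is False. Symbols are case-normalized to the
    species' nomenclature convention.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ExpressionSchemaError(f"DE table missing mandatory columns: {missing}")

    empty = df["Gene.symbol"].isna() | (df["Gene.symbol"].astype(str).str.strip() == "")
    if empty.any():
        logger.warning(
            "%s: dropping %d rows with empty Gene.symbol", accession, int(empty.sum())
        )
        df = df[~empty]

    calls: list[ExpressionCall] = []
    for _, row in df.iterrows():
        calls.append(
            ExpressionCall(
                gene_symbol=normalize_symbol(str(row["Gene.symbol"]), species),
                species=species,
                dataset_accession=accession,
                log_fold_change=float(row["logFC"]),
                p_value=float(row["P.Value"]),
                adjusted_p=float(row["adj.P.Val"])
                if "adj.P.Val" in df.columns and pd.notna(row.get("adj.P.Val"))
                else None,
            )
        )
    if collapse_probes:
        best: dict[str, ExpressionCall] = {}
        for call in calls:
            prev = best.get(call.gene_symbol)
            if prev is None or call.p_value < prev.p_value:
                best[call.gene_symbol] = call
        calls = [best[k] for k in sorted(best)]
    return calls


def call_direction(
    call: ExpressionCall, alpha: float = 0.05, use_adjusted: bool = False
) -> str:
    """up / down / ns. A zero fold change with p <= alpha is ns (warned)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    p = call.adjusted_p if use_adjusted and call.adjusted_p is not None else call.p_value
    if p > alpha:
        return NS
    if call.log_fold_change > 0:
        return UP
    if call.log_fold_change < 0:
        return DOWN
    logger.warning(
        "%s %s: significant call with zero fold change treated as ns",
        call.dataset_accession,
        call.gene_symbol,
    )
    return NS


def _species_directions(
    calls: Sequence[ExpressionCall], alpha: float, use_adjusted: bool
) -> set[str]:
    return {
        d
        for d in (call_direction(c, alpha, use_adjusted) for c in calls)
        if d != NS
    }


def classify_gene_concordance(
    gene: str,
    human_calls: Sequence[ExpressionCall],
    mouse_calls: Sequence[ExpressionCall],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> GeneConcordance:
    """Classify one gene. Calls must already be restricted to this gene
    (mouse calls under the orthology-mapped symbol). Raises ValueError when
    the gene has no calls in either species — such genes belong in the
    uncovered list, outside the summary denominator."""
    if not human_calls and not mouse_calls:
        raise ValueError(f"gene {gene!r} has no calls in either species")
    h_dirs = _species_directions(human_calls, alpha, use_adjusted)
    m_dirs = _species_directions(mouse_calls, alpha, use_adjusted)

    if {UP, DOWN} <= h_dirs or {UP, DOWN} <= m_dirs:
        category = INCONSISTENT_WITHIN
    elif not h_dirs and not m_dirs:
        category = NON_SIGNIFICANT
    elif h_dirs and not m_dirs:
        category = HUMAN_ONLY
    elif m_dirs and not h_dirs:
        category = MOUSE_ONLY
    elif h_dirs == m_dirs:
        category = SAME_PATTERN
    else:
        category = CONTRADICTORY_BETWEEN
    return GeneConcordance(gene, category, tuple(human_calls), tuple(mouse_calls))


@dataclass
class ConcordanceSet:
    classifications: list[GeneConcordance]
    uncovered: list[str] = field(default_factory=list)


def classify_all(
    human_calls: Iterable[ExpressionCall],
    mouse_calls: Iterable[ExpressionCall],
    omap: Optional[OrthologyMap] = None,
    genes: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> ConcordanceSet:
    """Group calls by human-space symbol and classify every covered gene.

    Mouse symbols are mapped into human space via the orthology map
    (case-convention fallback by default). ``genes`` optionally restricts
    and orders the genes considered (e.g. the gene list of a model);
    requested genes with no calls anywhere go to the uncovered list.
    """
    omap = omap or OrthologyMap()
    by_gene_h: dict[str, list[ExpressionCall]] = {}
    by_gene_m: dict[str, list[ExpressionCall]] = {}
    for call in human_calls:
        by_gene_h.setdefault(call.gene_symbol, []).append(call)
    for call in mouse_calls:
        for human_symbol in omap.map_symbol(call.gene_symbol, "human") or ():
            by_gene_m.setdefault(human_symbol, []).append(call)

    if genes is None:
        universe = sorted(set(by_gene_h) | set(by_gene_m))
    else:
        universe = [normalize_symbol(g, "human") for g in genes]

    classifications: list[GeneConcordance] = []
    uncovered: list[str] = []
    for gene in universe:
        h = by_gene_h.get(gene, [])
        m = by_gene_m.get(gene, [])
        if not h and not m:
            uncovered.append(gene)
            continue
        classifications.append(classify_gene_concordance(gene, h, m, alpha, use_adjusted))
    return ConcordanceSet(classifications, uncovered)


def summarize_concordance(classifications: Sequence[GeneConcordance]) -> dict:
    """Per-category counts and integer percentages (round half away).

    The denominator is the number of classified (covered) genes; an empty
    input yields an empty summary with no division.
    """
    if not classifications:
        return {"n": 0, "counts": {}, "percentages": {}}
    counts = {c: 0 for c in EXPRESSION_CATEGORIES}
    for gc in classifications:
        counts[gc.category] += 1
    n = len(classifications)
    percentages = {c: round_half_away(100.0 * k / n) for c, k in counts.items()}
    return {"n": n, "counts": counts, "percentages": percentages}


def concordance_to_table(result: ConcordanceSet) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": gc.gene_symbol,
            "category": gc.category,
            "n_human_calls": len(gc.human_calls),
            "n_mouse_calls": len(gc.mouse_calls),
        }
        for gc in result.classifications
    ] + [
        {"gene_symbol": g, "category": "uncovered", "n_human_calls": 0, "n_mouse_calls": 0}
        for g in result.uncovered
    ]
    return pd.DataFrame(rows)
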