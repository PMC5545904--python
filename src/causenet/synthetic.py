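"""Ground-truth fixture generators.

Two constructive generators make every pipeline stage testable without any
external download:

* :func:`generate_model_pair` builds a human model plus a mouse model that
  realizes exact per-category concordance counts (consistent /
  contradictory / unique_to_human), allocated by largest-remainder
  apportionment — category assignment is exact, not sampled; randomness
  affects only symbols, topology, and polarities.
* :func:`generate_expression_tables` builds per-species GEO2R-style call
  tables in which each gene's calls force its intended six-way concordance
  category under the classifier's precedence rules.

Both are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import CONSISTENT, CONTRADICTORY, UNIQUE_TO_HUMAN
from .expression import (
    CONTRADICTORY_BETWEEN,
    EXPRESSION_CATEGORIES,
    HUMAN_ONLY,
    INCONSISTENT_WITHIN,
    MOUSE_ONLY,
    NON_SIGNIFICANT,
    SAME_PATTERN,
)
from .model import (
    CausalEdge,
    CauseEffectModel,
    Entity,
    Function,
    FLIPPED_RELATION,
    Namespace,
    Relation,
)
from .orthology import _casefold_to


class SpecError(ValueError):
    pass


def largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` into integer counts proportional to ``weights``.

    Floors of the exact quotas are topped up in order of descending
    fractional remainder (ties broken by position), so the counts always sum
    to ``total`` exactly.
    """
    if total < 0:
        raise SpecError("total must be nonnegative")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise SpecError("weights must be nonnegative")
    if w.sum() == 0:
        raise SpecError("weights must not all be zero")
    quotas = total * w / w.sum()
    counts = np.floor(quotas).astype(int)
    remainder = int(total - counts.sum())
    order = sorted(range(len(w)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


@dataclass(frozen=True)
class ModelPairSpec:
    """Study conditions for a paired human/mouse model.

    Defaults mirror the cytokine-pathway comparison that motivates the
    package: a 73-edge human scope of which ~45% is molecular, classified
    with the molecular-level split 27% consistent / 15% contradictory /
    58% unique to human.
    """

    n_edges: int = 73
    consistent: float = 0.27
    contradictory: float = 0.15
    unique_to_human: float = 0.58
    n_mouse_only: int = 10
    molecular_fraction: float = 33 / 73
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges < 1:
            raise SpecError("n_edges must be >= 1")
        props = (self.consistent, self.contradictory, self.unique_to_human)
        if any(p < 0 for p in props):
            raise SpecError("proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise SpecError(f"proportions must sum to 1, got {sum(props)}")
        if not (0.0 <= self.molecular_fraction <= 1.0):
            raise SpecError("molecular_fraction must lie in [0, 1]")
        if self.n_mouse_only < 0:
            raise SpecError("n_mouse_only must be nonnegative")

    def category_counts(self) -> dict[str, int]:
        c, x, u = largest_remainder(
            self.n_edges, (self.consistent, self.contradictory, self.unique_to_human)
        )
        return {CONSISTENT: c, CONTRADICTORY: x, UNIQUE_TO_HUMAN: u}


_POLAR_RELATIONS = (Relation.INCREASES, Relation.DECREASES)


def _human_to_mouse(entity: Entity) -> Entity:
    if entity.namespace is Namespace.HGNC:
        return Entity(
            entity.function,
            Namespace.MGI,
            _casefold_to(entity.identifier, "mouse"),
            entity.modification,
            entity.activity,
        )
    return entity


def generate_model_pair(
    spec: ModelPairSpec,
) -> tuple[CauseEffectModel, CauseEffectModel, dict[tuple[str, str, str], str]]:
    """Build (human model, mouse model, truth labels per human edge triple).

    The human model has ``n_edges`` polar edges over synthetic HGNC-style
    symbols plus bioprocess/cell-population nodes according to
    ``molecular_fraction``. The mouse model is derived edge-by-edge from the
    truth label: keep the sign (consistent), flip it (contradictory), or
    omit the edge (unique_to_human); ``n_mouse_only`` extra edges over
    mouse-only symbols are appended. No two human edges share an ordered
    endpoint pair, so the classifier's category recovery is exact.
    """
    rng = np.random.default_rng(spec.seed)
    n_mol, n_cell = largest_remainder(
        spec.n_edges, (spec.molecular_fraction, 1.0 - spec.molecular_fraction)
    )

    n_symbols = max(6, int(np.ceil(2.5 * np.sqrt(spec.n_edges + spec.n_mouse_only))))
    proteins = [
        Entity(Function.PROTEIN, Namespace.HGNC, f"SYG{i + 1}") for i in range(n_symbols)
    ]
    n_ctx = max(3, n_symbols // 3)
    processes = [
        Entity(Function.BIOPROCESS, Namespace.GOBP, f"synthetic process {i + 1}")
        for i in range(n_ctx)
    ]
    cells = [
        Entity(Function.CELL_POPULATION, Namespace.MESH, f"synthetic cell {i + 1}")
        for i in range(n_ctx)
    ]
    cellular_nodes = processes + cells

    def pick(pool: list[Entity]) -> Entity:
        return pool[int(rng.integers(len(pool)))]

    used_pairs: set[tuple[str, str]] = set()
    human_edges: list[CausalEdge] = []
    for kind in [True] * n_mol + [False] * n_cell:
        for _ in range(10_000):
            if kind:  # molecular: protein -> protein
                subj, obj = pick(proteins), pick(proteins)
            else:  # cellular: a protein and a bioprocess/cell node, either role
                a, b = pick(proteins), pick(cellular_nodes)
                subj, obj = (a, b) if rng.random() < 0.5 else (b, a)
            pair = (subj.key(), obj.key())
            if subj.key() == obj.key() or pair in used_pairs:
                continue
            used_pairs.add(pair)
            relation = _POLAR_RELATIONS[int(rng.integers(2))]
            human_edges.append(CausalEdge(subj, relation, obj, species="human"))
            break
        else:  # pragma: no cover - pool sizes prevent this
            raise SpecError("node pool exhausted while sampling unique edges")

    counts = spec.category_counts()
    labels = (
        [CONSISTENT] * counts[CONSISTENT]
        + [CONTRADICTORY] * counts[CONTRADICTORY]
        + [UNIQUE_TO_HUMAN] * counts[UNIQUE_TO_HUMAN]
    )
    label_order = rng.permutation(len(labels))
    truth: dict[tuple[str, str, str], str] = {}

    human = CauseEffectModel(species="human")
    mouse = CauseEffectModel(species="mouse")
    for edge, idx in zip(human_edges, label_order):
        label = labels[idx]
        human.add_edge(edge)
        truth[edge.canonical_triple()] = label
        if label == UNIQUE_TO_HUMAN:
            continue
        relation = edge.relation if label == CONSISTENT else FLIPPED_RELATION[edge.relation]
        mouse.add_edge(
            CausalEdge(
                _human_to_mouse(edge.subject), relation, _human_to_mouse(edge.object), species="mouse"
            )
        )

    mouse_only_pool = [
        Entity(Function.PROTEIN, Namespace.MGI, f"Mog{i + 1}") for i in range(max(6, n_symbols))
    ]
    mo_pairs: set[tuple[str, str]] = set()
    for _ in range(spec.n_mouse_only):
        for _ in range(10_000):
            subj, obj = pick(mouse_only_pool), pick(mouse_only_pool)
            pair = (subj.key(), obj.key())
            if subj.key() == obj.key() or pair in mo_pairs:
                continue
            mo_pairs.add(pair)
            relation = _POLAR_RELATIONS[int(rng.integers(2))]
            mouse.add_edge(CausalEdge(subj, relation, obj, species="mouse"))
            break
    human.validate()
    mouse.validate()
    return human, mouse, truth


@dataclass(frozen=True)
class ExpressionSpec:
    """Per-category gene counts for the six-way expression concordance.

    Defaults are the printed study split over 100 genes (31 same-pattern,
    14 human-only, 19 mouse-only, 17 inconsistent-within, 7 contradictory-
    between, 12 non-significant), with three datasets per species as in the
    source comparison (three mouse accessions, three human accessions).
    ``effect`` is the |logFC| of a significant call.
    """

    counts: tuple[tuple[str, int], ...] = (
        (SAME_PATTERN, 31),
        (HUMAN_ONLY, 14),
        (MOUSE_ONLY, 19),
        (INCONSISTENT_WITHIN, 17),
        (CONTRADICTORY_BETWEEN, 7),
        (NON_SIGNIFICANT, 12),
    )
    n_datasets_human: int = 3
    n_datasets_mouse: int = 3
    alpha: float = 0.05
    effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        cdict = dict(self.counts)
        unknown = set(cdict) - set(EXPRESSION_CATEGORIES)
        if unknown:
            raise SpecError(f"unknown categories {sorted(unknown)}")
        if any(v < 0 for v in cdict.values()):
            raise SpecError("category counts must be nonnegative")
        if self.n_datasets_human < 1 or self.n_datasets_mouse < 1:
            raise SpecError("need at least one dataset per species")
        if not (0.0 < self.alpha < 1.0):
            raise SpecError("alpha must lie in (0, 1)")
        if (
            cdict.get(INCONSISTENT_WITHIN, 0) > 0
            and max(self.n_datasets_human, self.n_datasets_mouse) < 2
        ):
            raise SpecError(
                "inconsistent_within_species requires >=2 datasets in some species"
            )

    def count_dict(self) -> dict[str, int]:
        base = {c: 0 for c in EXPRESSION_CATEGORIES}
        base.update(dict(self.counts))
        return base


def generate_expression_tables(
    spec: ExpressionSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict[str, str]]:
    """Build ({human accession: table}, {mouse accession: table}, truth).

    Each gene appears in every dataset of both species; its calls are
    constructed so that the concordance classifier at ``spec.alpha``
    assigns exactly the intended category. Truth keys are human-space
    symbols.
    """
    rng = np.random.default_rng(spec.seed)
    alpha, effect = spec.alpha, spec.effect

    def p_sig() -> float:
        return float(alpha * rng.uniform(0.001, 0.8))

    def p_ns() -> float:
        return float(alpha + (1.0 - alpha) * rng.uniform(0.1, 0.95))

    def lfc_sig(direction: int) -> float:
        return float(direction * (effect + rng.exponential(0.3)))

    def lfc_ns() -> float:
        return float(rng.normal(0.0, 0.25))

    h_acc = [f"SYNH{i + 1}" for i in range(spec.n_datasets_human)]
    m_acc = [f"SYNM{i + 1}" for i in range(spec.n_datasets_mouse)]
    rows_h: dict[str, list[dict]] = {a: [] for a in h_acc}
    rows_m: dict[str, list[dict]] = {a: [] for a in m_acc}
    truth: dict[str, str] = {}

    gene_no = 0
    for category, count in spec.counts:
        for _ in range(count):
            gene_no += 1
            symbol = f"SYEG{gene_no}"
            truth[symbol] = category
            h_calls = [(lfc_ns(), p_ns()) for _ in h_acc]
            m_calls = [(lfc_ns(), p_ns()) for _ in m_acc]
            direction = int(rng.choice((-1, 1)))
            if category == SAME_PATTERN:
                h_calls[0] = (lfc_sig(direction), p_sig())
                m_calls[0] = (lfc_sig(direction), p_sig())
            elif category == HUMAN_ONLY:
                h_calls[0] = (lfc_sig(direction), p_sig())
            elif category == MOUSE_ONLY:
                m_calls[0] = (lfc_sig(direction), p_sig())
            elif category == INCONSISTENT_WITHIN:
                target = h_calls if spec.n_datasets_human >= 2 else m_calls
                target[0] = (lfc_sig(+1), p_sig())
                target[1] = (lfc_sig(-1), p_sig())
            elif category == CONTRADICTORY_BETWEEN:
                h_calls[0] = (lfc_sig(direction), p_sig())
                m_calls[0] = (lfc_sig(-direction), p_sig())
            # NON_SIGNIFICANT: leave every call ns
            for acc, (lfc, p) in zip(h_acc, h_calls):
                rows_h[acc].append(
                    {"Gene.symbol": symbol, "logFC": lfc, "P.Value": p, "adj.P.Val": min(1.0, p * 1.5)}
                )
            mouse_symbol = _casefold_to(symbol, "mouse")
            for acc, (lfc, p) in zip(m_acc, m_calls):
                rows_m[acc].append(
                    {"Gene.symbol": mouse_symbol, "logFC": lfc, "P.Value": p, "adj.P.Val": min(1.0, p * 1.5)}
                )

    return (
        {a: pd.DataFrame(rows_h[a]) for a in h_acc},
        {a: pd.DataFrame(rows_m[a]) for a in m_acc},
        truth,
    )
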