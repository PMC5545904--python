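"""Reading and writing cause-and-effect models.

Two on-disk dialects carry the same semantics:

* a BEL-subset script (one statement per line, ``SET Citation``/``SET
  Evidence`` annotation lines, term functions p/g/a/bp/complex/act/pmod plus
  a ``cell()`` function for cell-population nodes);
* a flat TSV edge table (one edge per row, explicit function/namespace/id
  columns).

Models can also be exported to SIF and GraphML and round-tripped through a
JSON document used by the command-line interface.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, TextIO, Union

import networkx as nx
import pandas as pd

from .model import (
    CODE_FUNCTION,
    FUNCTION_CODE,
    POLARITY,
    CausalEdge,
    CauseEffectModel,
    Entity,
    Evidence,
    Function,
    ModelValidationError,
    Namespace,
    Relation,
)

logger = logging.getLogger(__name__)

Pathish = Union[str, Path]


class BELParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_RELATION_ALIASES = {
    "->": Relation.INCREASES,
    "=>": Relation.DIRECTLY_INCREASES,
    "-|": Relation.DECREASES,
    "=|": Relation.DIRECTLY_DECREASES,
    "--": Relation.ASSOCIATION,
}
_RELATIONS = {r.value: r for r in Relation} | _RELATION_ALIASES

# Term functions of the dialect. act() wraps a p()/g() term; pmod() appears
# only as an argument of p()/g().
_TERM_FUNCTIONS = {"p", "g", "a", "bp", "complex", "act", "pmod", "cell"}

# Unicode names normalised to stable ASCII identifiers.
_IDENTIFIER_ALIASES = {"Aβ": "amyloid-beta", "Abeta": "amyloid-beta"}


def _tokenize_term(text: str, pos: int, line_no: Optional[int]) -> tuple[dict, int]:
    """Parse one term ``func(arg, ...)`` starting at ``pos``.

    Returns a nested dict {func, args} where args are strings (namespace:id
    parts, quoted strings) or nested term dicts.
    """
    start = pos
    while pos < len(text) and (text[pos].isalnum() or text[pos] == "_"):
        pos += 1
    func = text[start:pos]
    if func not in _TERM_FUNCTIONS:
        raise BELParseError(f"unsupported term function {func!r}", line_no)
    if pos >= len(text) or text[pos] != "(":
        raise BELParseError(f"expected '(' after {func!r}", line_no)
    pos += 1
    args: list = []
    current = ""

    def flush() -> None:
        nonlocal current
        token = current.strip()
        if token:
            args.append(token)
        current = ""

    while pos < len(text):
        ch = text[pos]
        if ch == '"':
            end = text.find('"', pos + 1)
            if end < 0:
                raise BELParseError("unterminated quoted string", line_no)
            current += text[pos : end + 1]
            pos = end + 1
        elif ch == "," :
            flush()
            pos += 1
        elif ch == ")":
            flush()
            return {"func": func, "args": args}, pos + 1
        elif ch.isalpha() and not current.strip():
            # Possible nested term: look ahead for func(
            probe = pos
            while probe < len(text) and (text[probe].isalnum() or text[probe] == "_"):
                probe += 1
            if probe < len(text) and text[probe] == "(" and text[pos:probe] in _TERM_FUNCTIONS:
                sub, pos = _tokenize_term(text, pos, line_no)
                args.append(sub)
            else:
                current += ch
                pos += 1
        else:
            current += ch
            pos += 1
    raise BELParseError(f"unterminated term {func!r}", line_no)


def _unquote(token: str) -> str:
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return _IDENTIFIER_ALIASES.get(token, token)


def _split_ns_id(token: str, line_no: Optional[int]) -> tuple[Namespace, str]:
    if ":" not in token:
        raise BELParseError(f"expected NAMESPACE:identifier, got {token!r}", line_no)
    ns, ident = token.split(":", 1)
    try:
        namespace = Namespace(ns)
    except ValueError:
        raise BELParseError(f"unknown namespace {ns!r}", line_no) from None
    ident = _unquote(ident)
    if not ident:
        raise BELParseError("empty identifier", line_no)
    return namespace, ident


def _term_to_entity(term: dict, line_no: Optional[int]) -> Entity:
    func = term["func"]
    if func == "act":
        if len(term["args"]) != 1 or not isinstance(term["args"][0], dict):
            raise BELParseError("act() requires a single inner term", line_no)
        inner = _term_to_entity(term["args"][0], line_no)
        return Entity(inner.function, inner.namespace, inner.identifier, inner.modification, True)
    if func == "pmod":
        raise BELParseError("pmod() only valid inside p()/g()", line_no)
    function = CODE_FUNCTION[func]
    ns_args = [a for a in term["args"] if isinstance(a, str)]
    mods = [a for a in term["args"] if isinstance(a, dict)]
    if len(ns_args) != 1:
        raise BELParseError(f"{func}() requires exactly one NAMESPACE:identifier", line_no)
    namespace, ident = _split_ns_id(ns_args[0], line_no)
    modification: Optional[str] = None
    for mod in mods:
        if mod["func"] != "pmod":
            raise BELParseError(f"unexpected nested term {mod['func']}() in {func}()", line_no)
        if function not in (Function.PROTEIN, Function.GENE):
            raise BELParseError("pmod() only allowed on p()/g() terms", line_no)
        modification = ",".join(_unquote(a) for a in mod["args"] if isinstance(a, str))
    return Entity(function, namespace, ident, modification or None, False)


def _parse_statement(line: str, line_no: Optional[int]) -> tuple[Entity, Relation, Entity]:
    term, pos = _tokenize_term(line, 0, line_no)
    subject = _term_to_entity(term, line_no)
    rest = line[pos:].strip()
    if not rest:
        raise BELParseError("statement has no relation/object", line_no)
    rel_token, _, obj_text = rest.partition(" ")
    if rel_token not in _RELATIONS:
        raise BELParseError(f"unsupported relation {rel_token!r}", line_no)
    relation = _RELATIONS[rel_token]
    obj_text = obj_text.strip()
    if not obj_text:
        raise BELParseError("statement has no object term", line_no)
    obj_term, end = _tokenize_term(obj_text, 0, line_no)
    if obj_text[end:].strip():
        raise BELParseError(f"trailing content after object term: {obj_text[end:].strip()!r}", line_no)
    obj = _term_to_entity(obj_term, line_no)
    return subject, relation, obj


def parse_term(text: str) -> Entity:
    """Parse a single dialect term (e.g. ``p(HGNC:PTGS2)``) into an Entity."""
    term, end = _tokenize_term(text.strip(), 0, None)
    if text.strip()[end:]:
        raise BELParseError(f"trailing content after term: {text.strip()[end:]!r}")
    return _term_to_entity(term, None)


def parse_bel_script(text: str, species: Optional[str] = None) -> CauseEffectModel:
    """Parse a BEL-subset document into a model.

    The species may be supplied as an argument, declared in a header comment
    (``# species: human``) or via ``SET Species = human``; when the document
    uses exactly one of the HGNC/MGI namespaces it is inferred. A document
    mixing HGNC and MGI namespaces without an explicit declaration is
    rejected.
    """
    declared = species
    citation: Optional[str] = None
    evidence_text: Optional[str] = None
    parsed: list[tuple[Entity, Relation, Entity, Optional[str], Optional[str]]] = []
    seen_species: set[str] = set()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            lowered = body.lower()
            if lowered.startswith("species"):
                value = body.split(":", 1)[-1].split("=", 1)[-1].strip().lower()
                if value in ("human", "mouse"):
                    declared = declared or value
            continue
        if line.startswith("SET "):
            key, _, value = line[4:].partition("=")
            key = key.strip().lower()
            value = _unquote(value.strip())
            if key == "citation":
                citation = value or None
            elif key == "evidence" or key == "support":
                evidence_text = value or None
            elif key == "species":
                value_l = value.lower()
                if value_l not in ("human", "mouse"):
                    raise BELParseError(f"unknown species {value!r}", line_no)
                declared = declared or value_l
            else:
                logger.warning("line %d: ignoring unsupported annotation SET %s", line_no, key)
            continue
        if line.startswith("UNSET "):
            key = line[6:].strip().lower()
            if key == "citation":
                citation = None
            elif key in ("evidence", "support"):
                evidence_text = None
            continue
        if line.startswith("DEFINE "):
            logger.warning("line %d: ignoring unsupported DEFINE line", line_no)
            continue
        subject, relation, obj = _parse_statement(line, line_no)
        for endpoint in (subject, obj):
            if endpoint.species is not None:
                seen_species.add(endpoint.species)
        parsed.append((subject, relation, obj, citation, evidence_text))

    if declared is None:
        if len(seen_species) == 1:
            declared = next(iter(seen_species))
        elif len(seen_species) > 1:
            raise ModelValidationError(
                "document mixes HGNC and MGI namespaces without an explicit species declaration"
            )
        else:
            raise ModelValidationError(
                "species is undeclared and cannot be inferred from namespaces"
            )
    if seen_species - {declared}:
        raise ModelValidationError(
            f"document declared species {declared!r} but uses "
            f"{sorted(seen_species - {declared})} namespaces"
        )

    model = CauseEffectModel(species=declared)
    for order, (subject, relation, obj, cit, ev) in enumerate(parsed):
        model.add_edge(
            CausalEdge(
                subject,
                relation,
                obj,
                species=declared,
                evidence=Evidence(cit, ev, order) if (cit or ev) or True else None,
            )
        )
    model.validate()
    return model


def _render_identifier(ident: str) -> str:
    if ident.isalnum() or all(c.isalnum() or c in "_-." for c in ident):
        if " " not in ident:
            return ident
    return f'"{ident}"'


def render_term(entity: Entity) -> str:
    """Render an Entity back to its dialect term."""
    inner = f"{FUNCTION_CODE[entity.function]}({entity.namespace.value}:{_render_identifier(entity.identifier)}"
    if entity.modification:
        parts = ", ".join(entity.modification.split(","))
        inner += f", pmod({parts})"
    inner += ")"
    if entity.activity:
        return f"act({inner})"
    return inner


def write_bel_script(model: CauseEffectModel) -> str:
    """Serialize a model to the BEL-subset dialect.

    Output is deterministic: statements sorted by their canonical
    (subject, relation, object) string; citation/evidence annotations are
    emitted as SET lines before each statement that carries them.
    """
    lines = [f"# species: {model.species}"]
    current_citation: Optional[str] = None
    current_evidence: Optional[str] = None

    def sort_key(e: CausalEdge):
        return e.canonical_triple(strict=True)

    for edge in sorted(model.edges, key=sort_key):
        cit = edge.evidence.citation if edge.evidence else None
        ev = edge.evidence.text if edge.evidence else None
        if cit != current_citation:
            lines.append(f'SET Citation = "{cit}"' if cit else "UNSET Citation")
            current_citation = cit
        if ev != current_evidence:
            lines.append(f'SET Evidence = "{ev}"' if ev else "UNSET Evidence")
            current_evidence = ev
        lines.append(f"{render_term(edge.subject)} {edge.relation.value} {render_term(edge.object)}")
    # isolated entities (declared but unconnected) are not expressible in the
    # statement dialect; they round-trip through the TSV/JSON forms instead
    return "\n".join(lines) + "\n"


_TSV_REQUIRED = [
    "subject_function",
    "subject_ns",
    "subject_id",
    "relation",
    "object_function",
    "object_ns",
    "object_id",
    "species",
]


class SchemaError(ValueError):
    pass


def _entity_from_row(row: pd.Series, side: str, row_no: int) -> Entity:
    try:
        function = Function(row[f"{side}_function"])
        namespace = Namespace(row[f"{side}_ns"])
    except ValueError as exc:
        raise SchemaError(f"row {row_no}: {exc}") from None
    modification = row.get(f"{side}_modification")
    if isinstance(modification, float) and pd.isna(modification):
        modification = None
    activity = bool(row.get(f"{side}_activity", False)) and str(
        row.get(f"{side}_activity")
    ).lower() not in ("0", "false", "nan", "")
    return Entity(function, namespace, str(row[f"{side}_id"]), modification or None, activity)


def load_edge_table(source: Union[Pathish, TextIO, pd.DataFrame]) -> CauseEffectModel:
    """Load a model from a flat TSV edge table.

    Semantics are identical to :func:`parse_bel_script`; blank lines and
    ``#`` comments are ignored. All rows must carry the same species.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", skip_blank_lines=True, dtype=str)
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"edge table missing mandatory columns: {missing}")
    species_values = set(df["species"].dropna().unique())
    if len(species_values) > 1:
        raise SchemaError(f"edge table mixes species: {sorted(species_values)}")
    if df.empty:
        raise SchemaError("edge table has no rows; species undeterminable")
    species = next(iter(species_values))
    if species not in ("human", "mouse"):
        raise SchemaError(f"unknown species {species!r}")

    model = CauseEffectModel(species=species)
    bad_rows: list[str] = []
    for order, (idx, row) in enumerate(df.iterrows()):
        try:
            subject = _entity_from_row(row, "subject", idx)
            obj = _entity_from_row(row, "object", idx)
            relation = Relation(row["relation"])
        except (SchemaError, ValueError, ModelValidationError) as exc:
            bad_rows.append(f"row {idx}: {exc}")
            continue
        citation = row.get("citation")
        if isinstance(citation, float) and pd.isna(citation):
            citation = None
        ev = row.get("evidence")
        if isinstance(ev, float) and pd.isna(ev):
            ev = None
        model.add_edge(
            CausalEdge(subject, relation, obj, species=species, evidence=Evidence(citation, ev, order))
        )
    if bad_rows:
        raise SchemaError("invalid rows in edge table:\n" + "\n".join(bad_rows))
    model.validate()
    return model


def write_edge_table(model: CauseEffectModel) -> pd.DataFrame:
    """Serialize a model to the flat TSV edge-table layout (as a DataFrame)."""
    rows = []
    for edge in sorted(model.edges, key=lambda e: e.canonical_triple(strict=True)):
        rows.append(
            {
                "subject_function": edge.subject.function.value,
                "subject_ns": edge.subject.namespace.value,
                "subject_id": edge.subject.identifier,
                "subject_modification": edge.subject.modification,
                "subject_activity": edge.subject.activity,
                "relation": edge.relation.value,
                "object_function": edge.object.function.value,
                "object_ns": edge.object.namespace.value,
                "object_id": edge.object.identifier,
                "object_modification": edge.object.modification,
                "object_activity": edge.object.activity,
                "species": edge.species,
                "citation": edge.evidence.citation if edge.evidence else None,
                "evidence": edge.evidence.text if edge.evidence else None,
            }
        )
    return pd.DataFrame(rows)


def model_stats(model: CauseEffectModel) -> dict:
    """Pure summary: node/edge/statement counts and per-function node counts.

    Edge count counts distinct (subject, relation, object) triples; the node
    count is the union of edge endpoints plus isolated declared entities.
    """
    by_function: dict[str, int] = {}
    for entity in model.entities:
        by_function[entity.function.value] = by_function.get(entity.function.value, 0) + 1
    return {
        "species": model.species,
        "nodes": len(model.entities),
        "edges": len(model.distinct_triples()),
        "statements": model.statement_count,
        "nodes_by_function": dict(sorted(by_function.items())),
    }


def to_networkx(model: CauseEffectModel, strict: bool = False) -> nx.MultiDiGraph:
    """Model as a networkx MultiDiGraph keyed by node key.

    One graph edge per distinct triple; association edges appear once in
    canonical (lexicographic) orientation.
    """
    g = nx.MultiDiGraph(species=model.species)
    key_to_entity: dict[str, Entity] = {}
    for entity in model.entities:
        k = entity.key(strict)
        key_to_entity.setdefault(k, entity)
    for k, entity in key_to_entity.items():
        g.add_node(
            k,
            function=entity.function.value,
            namespace=entity.namespace.value,
            identifier=entity.identifier,
        )
    for s, rel, o in sorted(model.distinct_triples(strict)):
        g.add_edge(s, o, relation=rel, polarity=POLARITY[Relation(rel)])
    return g


def export_graph(model: CauseEffectModel, fmt: str, path: Pathish) -> None:
    """Export to SIF or GraphML. SIF rows are subject<TAB>relation<TAB>object."""
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        lines = [f"{s}\t{rel}\t{o}" for s, rel, o in sorted(model.distinct_triples())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(model), path)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use 'sif' or 'graphml')")


# -- JSON round trip (CLI artifact format) -----------------------------------

def _entity_to_dict(e: Entity) -> dict:
    return {
        "function": e.function.value,
        "namespace": e.namespace.value,
        "identifier": e.identifier,
        "modification": e.modification,
        "activity": e.activity,
    }


def _entity_from_dict(d: dict) -> Entity:
    return Entity(
        Function(d["function"]),
        Namespace(d["namespace"]),
        d["identifier"],
        d.get("modification"),
        bool(d.get("activity", False)),
    )


def model_to_dict(model: CauseEffectModel) -> dict:
    return {
        "species": model.species,
        "entities": [
            _entity_to_dict(e) for e in sorted(model.entities, key=lambda x: x.key(True))
        ],
        "edges": [
            {
                "subject": _entity_to_dict(e.subject),
                "relation": e.relation.value,
                "object": _entity_to_dict(e.object),
                "citation": e.evidence.citation if e.evidence else None,
                "evidence": e.evidence.text if e.evidence else None,
            }
            for e in model.edges
        ],
    }


def model_from_dict(d: dict) -> CauseEffectModel:
    model = CauseEffectModel(species=d["species"])
    for ed in d.get("entities", []):
        model.add_entity(_entity_from_dict(ed))
    for order, ed in enumerate(d.get("edges", [])):
        model.add_edge(
            CausalEdge(
                _entity_from_dict(ed["subject"]),
                Relation(ed["relation"]),
                _entity_from_dict(ed["object"]),
                species=d["species"],
                evidence=Evidence(ed.get("citation"), ed.get("evidence"), order),
            )
        )
    model.validate()
    return model


def save_model_json(model: CauseEffectModel, path: Pathish) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model_json(path: Pathish) -> CauseEffectModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def load_model(path: Pathish, species: Optional[str] = None) -> CauseEffectModel:
    """Dispatch on extension: .bel, .tsv/.txt, .json."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bel":
        return parse_bel_script(path.read_text(), species=species)
    if suffix in (".tsv", ".txt"):
        return load_edge_table(path)
    if suffix == ".json":
        return load_model_json(path)
    raise ValueError(f"cannot infer model format from extension {suffix!r}")
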