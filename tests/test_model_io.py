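"""BEL-subset and edge-table I/O: parsing, round trips, stats, export."""

import io as _io

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causenet.io import (
    BELParseError,
    SchemaError,
    export_graph,
    load_edge_table,
    model_from_dict,
    model_stats,
    model_to_dict,
    parse_bel_script,
    parse_term,
    to_networkx,
    write_bel_script,
    write_edge_table,
)
from causenet.model import (
    CausalEdge,
    CauseEffectModel,
    Entity,
    Function,
    ModelValidationError,
    Namespace,
    POLARITY,
    Relation,
)

from conftest import bioprocess, edge, model_from, protein


class TestParse:
    def test_single_statement(self):
        m = parse_bel_script('p(MGI:Ptgs2) increases a(CHEBI:"amyloid-beta")')
        assert m.species == "mouse"
        assert m.statement_count == 1
        e = m.edges[0]
        assert e.polarity == +1
        assert e.subject == Entity(Function.PROTEIN, Namespace.MGI, "Ptgs2")
        assert e.object == Entity(Function.CHEMICAL, Namespace.CHEBI, "amyloid-beta")

    def test_empty_document(self):
        m = parse_bel_script("", species="human")
        assert (len(m.entities), len(m.edges), m.statement_count) == (0, 0, 0)

    def test_decorations_are_entity_level_not_nodes(self):
        m = parse_bel_script(
            "p(HGNC:PDPK1) increases p(HGNC:AKT1, pmod(Ph))\n"
            "p(HGNC:PDPK1) increases act(p(HGNC:IL4))"
        )
        akt = next(e.object for e in m.edges if e.object.identifier == "AKT1")
        il4 = next(e.object for e in m.edges if e.object.identifier == "IL4")
        assert akt.modification == "Ph" and not akt.activity
        assert il4.activity and il4.modification is None
        assert len(m.entities) == 3  # wrappers are decorations, not extra nodes

    def test_unicode_identifier_normalized(self):
        m = parse_bel_script('p(MGI:Ptgs2) increases a(CHEBI:"Aβ")')
        assert m.edges[0].object.identifier == "amyloid-beta"

    def test_evidence_annotations_attach_to_statements(self):
        text = (
            'SET Citation = "PMID:1"\nSET Evidence = "some sentence"\n'
            "p(HGNC:TNF) increases p(HGNC:NFKB1)\n"
            "UNSET Citation\n"
            "p(HGNC:NFKB1) increases p(HGNC:PTGS2)\n"
        )
        m = parse_bel_script(text)
        assert m.edges[0].evidence.citation == "PMID:1"
        assert m.edges[0].evidence.text == "some sentence"
        assert m.edges[1].evidence.citation is None
        assert [e.evidence.order for e in m.edges] == [0, 1]

    def test_unknown_annotation_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = parse_bel_script('SET Tissue = "cortex"\np(HGNC:TNF) increases p(HGNC:NFKB1)')
        assert m.statement_count == 1
        assert "tissue" in caplog.text.lower()

    def test_malformed_statement_reports_line(self):
        with pytest.raises(BELParseError, match="line 2"):
            parse_bel_script("p(HGNC:TNF) increases p(HGNC:NFKB1)\np(HGNC:TNF) increases")

    def test_unsupported_relation_named(self):
        with pytest.raises(BELParseError, match="regulates"):
            parse_bel_script("p(HGNC:TNF) regulates p(HGNC:NFKB1)")

    def test_unsupported_function_rejected(self):
        with pytest.raises(BELParseError, match="kin"):
            parse_bel_script("kin(HGNC:TNF) increases p(HGNC:NFKB1)")

    def test_mixed_species_without_declaration_rejected(self):
        with pytest.raises(ModelValidationError, match="species"):
            parse_bel_script("p(HGNC:TNF) increases p(MGI:Nfkb1)")

    def test_header_comment_declares_species(self):
        m = parse_bel_script('# species: mouse\nbp(GOBP:"autophagy") decreases a(CHEBI:"amyloid-beta")')
        assert m.species == "mouse"

    def test_neutral_only_without_declaration_rejected(self):
        with pytest.raises(ModelValidationError):
            parse_bel_script('bp(GOBP:"autophagy") decreases a(CHEBI:"amyloid-beta")')

    def test_relation_arrow_aliases(self):
        m = parse_bel_script("p(HGNC:TNF) -| p(HGNC:NFKB1)")
        assert m.edges[0].relation is Relation.DECREASES

    def test_parse_term_roundtrip_modification_fields(self):
        e = parse_term("p(HGNC:TSC2, pmod(Ph, Thr, 1462))")
        assert e.modification == "Ph,Thr,1462"


class TestWriteRoundTrip:
    def test_write_then_parse_identity(self, tiny_pair):
        human, _ = tiny_pair
        assert parse_bel_script(write_bel_script(human)) == human

    def test_output_sorted_and_deterministic(self):
        a, b, c = protein("A"), protein("B"), protein("C")
        m = model_from("human", edge(a, "decreases", c), edge(a, "increases", b))
        lines = [l for l in write_bel_script(m).splitlines() if not l.startswith(("#", "SET", "UNSET"))]
        assert lines == sorted(lines)
        assert write_bel_script(m) == write_bel_script(m)

    def test_association_single_line(self):
        m = model_from("human", edge(protein("A"), "association", protein("B")))
        lines = [l for l in write_bel_script(m).splitlines() if "association" in l]
        assert len(lines) == 1

    def test_quoted_identifier_roundtrip(self):
        m = model_from("human", edge(protein("IL4"), "decreases", bioprocess("inflammatory response")))
        assert parse_bel_script(write_bel_script(m)) == m

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_roundtrip_on_random_models(self, data):
        symbols = st.sampled_from(["AKT1", "TSC2", "MTOR", "RHEB", "TNF", "IL4"])
        rels = st.sampled_from(list(Relation))
        n = data.draw(st.integers(1, 8))
        m = CauseEffectModel(species="human")
        for _ in range(n):
            s, o = data.draw(symbols), data.draw(symbols)
            if s == o:
                continue
            mod = data.draw(st.sampled_from([None, "Ph"]))
            m.add_edge(
                CausalEdge(
                    protein(s, modification=mod),
                    data.draw(rels),
                    protein(o),
                    species="human",
                )
            )
        assert parse_bel_script(write_bel_script(m)) == m


class TestEdgeTable:
    TSV = (
        "subject_function\tsubject_ns\tsubject_id\trelation\t"
        "object_function\tobject_ns\tobject_id\tspecies\n"
        "protein\tHGNC\tTNF\tincreases\tprotein\tHGNC\tNFKB1\thuman\n"
        "protein\tHGNC\tNFKB1\tdecreases\tprotein\tHGNC\tPTGS2\thuman\n"
        "protein\tHGNC\tIL4\tdecreases\tbioprocess\tGOBP\tinflammatory response\thuman\n"
    )

    def test_three_rows(self):
        m = load_edge_table(_io.StringIO(self.TSV))
        assert len(m.edges) == 3
        assert len(m.entities) <= 6

    def test_decreases_polarity(self):
        m = load_edge_table(_io.StringIO(self.TSV))
        assert m.edges[1].polarity == -1

    def test_duplicate_row_is_multiset(self):
        row = "protein\tHGNC\tTNF\tincreases\tprotein\tHGNC\tNFKB1\thuman\n"
        header = self.TSV.splitlines()[0] + "\n"
        m = load_edge_table(_io.StringIO(header + row + row))
        assert m.statement_count == 2
        assert len(m.distinct_triples()) == 1
        assert len(m.entities) == 2

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError, match="relation"):
            load_edge_table(pd.DataFrame({"subject_function": ["protein"]}))

    def test_unknown_enum_lists_rows(self):
        bad = self.TSV.replace("increases", "promotes", 1)
        with pytest.raises(SchemaError, match="row 0"):
            load_edge_table(_io.StringIO(bad))

    def test_equivalent_to_bel_parse(self):
        bel = (
            "p(HGNC:TNF) increases p(HGNC:NFKB1)\n"
            "p(HGNC:NFKB1) decreases p(HGNC:PTGS2)\n"
            'p(HGNC:IL4) decreases bp(GOBP:"inflammatory response")\n'
        )
        assert load_edge_table(_io.StringIO(self.TSV)) == parse_bel_script(bel)

    def test_table_roundtrip(self, tiny_pair):
        human, _ = tiny_pair
        assert load_edge_table(write_edge_table(human)) == human


class TestStatsExport:
    def test_counts(self, tiny_pair):
        human, _ = tiny_pair
        s = model_stats(human)
        assert s["nodes"] == 5 and s["edges"] == 3 and s["statements"] == 3
        assert s["nodes_by_function"] == {"protein": 4, "bioprocess": 1}

    def test_empty_model_zero(self):
        s = model_stats(CauseEffectModel(species="human"))
        assert (s["nodes"], s["edges"], s["statements"]) == (0, 0, 0)

    def test_duplicate_statement_counts_once_as_edge(self):
        e = edge(protein("A"), "increases", protein("B"))
        m = model_from("human", e, edge(protein("A"), "increases", protein("B")))
        s = model_stats(m)
        assert s["edges"] == 1 and s["statements"] == 2

    def test_sif_one_line_per_edge(self, tmp_path, tiny_pair):
        human, _ = tiny_pair
        out = tmp_path / "m.sif"
        export_graph(human, "sif", out)
        lines = out.read_text().splitlines()
        assert len(lines) == 3
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_association_exported_once_canonical(self, tmp_path):
        m = model_from("human", edge(protein("B"), "association", protein("A")))
        out = tmp_path / "m.sif"
        export_graph(m, "sif", out)
        (line,) = out.read_text().splitlines()
        assert line.split("\t")[0] == "p:HGNC:A"  # lexicographic orientation

    def test_graphml_preserves_polarity_multiset(self, tmp_path, tiny_pair):
        human, _ = tiny_pair
        out = tmp_path / "m.graphml"
        export_graph(human, "graphml", out)
        g = nx.read_graphml(out)
        polarities = sorted(d["polarity"] for *_, d in g.edges(data=True))
        expected = sorted(POLARITY[e.relation] for e in human.edges)
        assert polarities == expected

    def test_unsupported_format(self, tiny_pair):
        with pytest.raises(ValueError, match="unsupported"):
            export_graph(tiny_pair[0], "dot", "x.dot")

    def test_json_roundtrip_preserves_isolated_entities(self, tiny_pair):
        human, _ = tiny_pair
        human.add_entity(protein("GSK3B"))
        assert model_from_dict(model_to_dict(human)) == human
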