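"""Edge-level concordance classification and its invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causenet.concordance import (
    CELLULAR,
    CONSISTENT,
    CONTRADICTORY,
    MOLECULAR,
    UNIQUE_TO_HUMAN,
    ComparisonRecord,
    classify_edge,
    compare_models,
    round_half_away,
    stratify_level,
)
from causenet.model import CausalEdge, CauseEffectModel, Relation
from causenet.orthology import TABLE_ONLY, OrthologyMap, map_entity_candidates
from causenet.synthetic import ModelPairSpec, generate_model_pair

from conftest import bioprocess, cell, chemical, edge, model_from, protein


def brute_force_classify(human_edge, mouse_model, omap):
    """Independent oracle: enumerate every mouse edge and compare mapped
    endpoint keys directly."""
    subj = map_entity_candidates(human_edge.subject, omap, "mouse")
    obj = map_entity_candidates(human_edge.object, omap, "mouse")
    if not subj or not obj:
        return UNIQUE_TO_HUMAN
    skeys = {e.key() for e in subj}
    okeys = {e.key() for e in obj}
    polarities = set()
    for m in mouse_model.edges:
        ms, mo = m.subject.key(), m.object.key()
        forward = ms in skeys and mo in okeys
        backward = mo in skeys and ms in okeys
        if forward or (backward and (not m.is_directed or not human_edge.is_directed)):
            polarities.add(m.polarity)
    hp = human_edge.polarity
    if hp == 0:
        return CONSISTENT if polarities else UNIQUE_TO_HUMAN
    if hp in polarities:
        return CONSISTENT
    if -hp in polarities:
        return CONTRADICTORY
    if 0 in polarities:
        return CONSISTENT  # nonpolar support, default mode
    return UNIQUE_TO_HUMAN


class TestStratify:
    @pytest.mark.parametrize(
        "subject,obj,expected",
        [
            (protein("TNF"), protein("NFKB1"), MOLECULAR),
            (protein("PTGS2", "mouse"), bioprocess("inflammatory response"), CELLULAR),
            (cell("microglia"), protein("Tnf", "mouse"), CELLULAR),
            (protein("PTGS2"), chemical("amyloid-beta"), MOLECULAR),
            (bioprocess("autophagy"), bioprocess("phagocytosis"), CELLULAR),
        ],
    )
    def test_rule(self, subject, obj, expected):
        species = "mouse" if "mouse" in {subject.species, obj.species} else "human"
        assert stratify_level(edge(subject, "increases", obj, species=species)) == expected


class TestClassifyEdge:
    def test_same_sign_consistent(self, tiny_pair):
        human, mouse = tiny_pair
        rec = classify_edge(human.edges[0], mouse, OrthologyMap())
        assert rec.category == CONSISTENT and rec.mouse_match is not None

    def test_sign_flip_contradictory(self, tiny_pair):
        human, mouse = tiny_pair
        rec = classify_edge(human.edges[1], mouse, OrthologyMap())
        assert rec.category == CONTRADICTORY
        assert rec.mouse_match.polarity == -human.edges[1].polarity

    def test_absent_unique(self, tiny_pair):
        human, mouse = tiny_pair
        rec = classify_edge(human.edges[2], mouse, OrthologyMap())
        assert rec.category == UNIQUE_TO_HUMAN and rec.mouse_match is None

    def test_reversed_orientation_is_not_a_match(self):
        human = model_from("human", edge(protein("A"), "increases", protein("B")))
        mouse = model_from(
            "mouse", edge(protein("B", "mouse"), "increases", protein("A", "mouse"), species="mouse")
        )
        rec = classify_edge(human.edges[0], mouse, OrthologyMap())
        assert rec.category == UNIQUE_TO_HUMAN

    def test_association_mouse_support_flagged_nonpolar(self):
        human = model_from("human", edge(protein("A"), "increases", protein("B")))
        mouse = model_from(
            "mouse", edge(protein("A", "mouse"), "association", protein("B", "mouse"), species="mouse")
        )
        rec = classify_edge(human.edges[0], mouse, OrthologyMap())
        assert rec.category == CONSISTENT and rec.nonpolar_match
        rec2 = classify_edge(human.edges[0], mouse, OrthologyMap(), nonpolar_as_consistent=False)
        assert rec2.category == UNIQUE_TO_HUMAN and rec2.nonpolar_match

    def test_mixed_evidence_consistent_wins_with_flag(self):
        human = model_from("human", edge(protein("A"), "increases", protein("B")))
        mouse = model_from(
            "mouse",
            edge(protein("A", "mouse"), "increases", protein("B", "mouse"), species="mouse"),
            edge(protein("A", "mouse"), "decreases", protein("B", "mouse"), species="mouse"),
        )
        rec = classify_edge(human.edges[0], mouse, OrthologyMap())
        assert rec.category == CONSISTENT and rec.mixed_evidence

    def test_unmappable_endpoint_table_only_records_no_orthology(self, tiny_pair):
        human, mouse = tiny_pair
        rec = classify_edge(human.edges[0], mouse, OrthologyMap(policy=TABLE_ONLY))
        assert rec.category == UNIQUE_TO_HUMAN and rec.no_orthology

    def test_strict_mode_requires_decorations(self):
        human = model_from(
            "human", edge(protein("PDPK1"), "increases", protein("AKT1", modification="Ph"))
        )
        mouse = model_from(
            "mouse",
            edge(protein("Pdpk1", "mouse"), "increases", protein("Akt1", "mouse"), species="mouse"),
        )
        assert classify_edge(human.edges[0], mouse, OrthologyMap()).category == CONSISTENT
        assert (
            classify_edge(human.edges[0], mouse, OrthologyMap(), strict=True).category
            == UNIQUE_TO_HUMAN
        )


class TestCompareModels:
    def test_self_comparison_fully_consistent(self, tiny_pair):
        human, _ = tiny_pair
        spec_mouse = CauseEffectModel(species="mouse")
        from causenet.synthetic import _human_to_mouse

        for e in human.edges:
            spec_mouse.add_edge(
                CausalEdge(_human_to_mouse(e.subject), e.relation, _human_to_mouse(e.object), species="mouse")
            )
        result = compare_models(human, spec_mouse, OrthologyMap())
        for level, cats in result.summary.counts.items():
            assert cats[CONSISTENT] == result.summary.denominators[level]
        assert result.summary.percentages[MOLECULAR][CONSISTENT] == 100

    def test_empty_scope_no_division(self, tiny_pair):
        human, mouse = tiny_pair
        result = compare_models(human, mouse, OrthologyMap(), scope=[])
        assert result.records == [] and result.summary.denominators == {}

    def test_partition_and_denominators(self, tiny_pair):
        human, mouse = tiny_pair
        result = compare_models(human, mouse, OrthologyMap())
        for level, cats in result.summary.counts.items():
            assert sum(cats.values()) == result.summary.denominators[level]
        assert len(result.records) == len(human.distinct_triples())

    def test_percentages_sum_to_100ish(self):
        h, m, _ = generate_model_pair(ModelPairSpec(n_edges=41, seed=5))
        result = compare_models(h, m, OrthologyMap())
        for level, pcts in result.summary.percentages.items():
            assert abs(sum(pcts.values()) - 100) <= 2  # integer rounding slack

    def test_symmetry_roles_swap(self):
        h, m, _ = generate_model_pair(ModelPairSpec(n_edges=60, n_mouse_only=7, seed=11))
        fwd = compare_models(h, m, OrthologyMap())
        # swap roles: classify mouse edges against the human model
        rev = compare_models(m, h, OrthologyMap())
        fwd_counts = fwd.summary.total_counts()
        rev_counts = rev.summary.total_counts()
        assert fwd_counts[CONSISTENT] == rev_counts[CONSISTENT]
        assert fwd_counts[CONTRADICTORY] == rev_counts[CONTRADICTORY]
        assert fwd_counts[UNIQUE_TO_HUMAN] == sum(rev.mouse_only_counts.values())
        assert sum(fwd.mouse_only_counts.values()) == rev_counts[UNIQUE_TO_HUMAN]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_small_models(self, seed):
        h, m, _ = generate_model_pair(
            ModelPairSpec(n_edges=18, n_mouse_only=3, seed=seed)
        )
        for e in h.edges:
            expected = brute_force_classify(e, m, OrthologyMap())
            got = classify_edge(e, m, OrthologyMap()).category
            assert got == expected


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(27.27, 27), (57.57, 58), (62.5, 63), (0.5, 1), (-0.5, -1), (10.0, 10)]
    )
    def test_round_half_away(self, value, expected):
        assert round_half_away(value) == expected
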