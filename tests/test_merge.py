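"""Merging, dedup, rule collapse, cardinality, reconciliation, conflicts."""

import pytest

from sssomkit.curie import PrefixMap
from sssomkit.errors import PrefixClash
from sssomkit.merge import (
    ConflictKind,
    collapse_rules,
    compute_cardinality,
    dedup,
    detect_conflicts,
    merge,
    reconcile_unique_object,
)
from sssomkit.model import MappingSet
from sssomkit.registry import MatchType, PredicateModifier, Strength, predicate_class
from tests.conftest import mapping

PM = PrefixMap({"A": "https://example.org/a/", "B": "https://example.org/b/"})


def ms(rows, set_id="https://example.org/ms/m", pm=PM):
    return MappingSet(mapping_set_id=set_id, curie_map=pm, mappings=rows)


class TestMerge:
    def test_single_set_identity_of_rows(self):
        s = ms([mapping("A:1", "skos:exactMatch", "B:1")])
        merged = merge([s], "https://example.org/ms/new")
        assert merged.mappings == s.mappings
        assert merged.mapping_set_id == "https://example.org/ms/new"
        assert merged.see_also == ("https://example.org/ms/m",)

    def test_two_disjoint_sets(self):
        s1 = ms([mapping("A:1", "skos:exactMatch", "B:1")], set_id="https://example.org/s1")
        s2 = ms([mapping("A:2", "skos:exactMatch", "B:2")], set_id="https://example.org/s2",
                pm=PrefixMap({"A": "https://example.org/a/", "B": "https://example.org/b/",
                              "C": "https://example.org/c/"}))
        merged = merge([s1, s2], "https://example.org/both")
        assert len(merged.mappings) == 2
        assert set(merged.see_also) == {"https://example.org/s1", "https://example.org/s2"}
        assert "C" in merged.curie_map

    def test_prefix_clash_propagates(self):
        s1 = ms([], pm=PrefixMap({"A": "https://example.org/a/"}))
        s2 = ms([], pm=PrefixMap({"A": "https://example.org/other/"}))
        with pytest.raises(PrefixClash):
            merge([s1, s2], "https://example.org/x")

    def test_associative_up_to_row_order(self):
        sets = [ms([mapping(f"A:{i}", "skos:exactMatch", f"B:{i}")],
                   set_id=f"https://example.org/s{i}") for i in range(3)]
        left = merge([merge(sets[:2], "https://example.org/ab")] + [sets[2]],
                     "https://example.org/abc")
        right = merge([sets[0], merge(sets[1:], "https://example.org/bc")],
                      "https://example.org/abc")
        assert left.mappings == right.mappings


class TestDedup:
    def test_identical_rows_collapse(self):
        row = mapping("A:1", "skos:exactMatch", "B:1")
        assert len(dedup(ms([row, row])).mappings) == 1

    def test_distinct_rules_kept(self):
        r1 = mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical",
                     subject_match_field=["rdfs:label"], object_match_field=["rdfs:label"])
        r2 = mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical",
                     subject_match_field=["oboInOwl:hasExactSynonym"],
                     object_match_field=["oboInOwl:hasExactSynonym"])
        assert len(dedup(ms([r1, r2])).mappings) == 2

    def test_empty_and_idempotent(self):
        assert dedup(ms([])).mappings == []
        s = ms([mapping("A:1", "skos:exactMatch", "B:1")] * 3)
        assert dedup(dedup(s)).mappings == dedup(s).mappings


class TestCollapseRules:
    def test_confidence_max(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical", confidence=0.7),
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical", confidence=0.9),
        ]
        out = collapse_rules(ms(rows)).mappings
        assert len(out) == 1 and out[0].confidence == 0.9

    def test_mixed_match_types_become_complex(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical"),
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Logical"),
        ]
        assert collapse_rules(ms(rows)).mappings[0].match_type is MatchType.Complex

    def test_match_metadata_unioned(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical",
                    subject_match_field=["rdfs:label"], match_string=["limb"]),
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical",
                    subject_match_field=["oboInOwl:hasExactSynonym"], match_string=["limb"]),
        ]
        out = collapse_rules(ms(rows)).mappings[0]
        assert out.subject_match_field == ("rdfs:label", "oboInOwl:hasExactSynonym")
        assert out.match_string == ("limb",)

    def test_singleton_unchanged_and_idempotent(self):
        row = mapping("A:1", "skos:exactMatch", "B:1", confidence=0.5)
        s = ms([row])
        assert collapse_rules(s).mappings == [row]
        collapsed = collapse_rules(ms([row, mapping("A:1", "skos:exactMatch", "B:1")]))
        assert collapse_rules(collapsed).mappings == collapsed.mappings

    def test_negated_rows_group_separately(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:exactMatch", "B:1", predicate_modifier="Not"),
        ]
        assert len(collapse_rules(ms(rows)).mappings) == 2


class TestCardinality:
    def test_disjoint_pairs_are_one_to_one(self):
        out = compute_cardinality(
            ms([mapping("A:1", "skos:exactMatch", "B:1"),
                mapping("A:2", "skos:exactMatch", "B:2")])
        )
        assert [m.mapping_cardinality for m in out.mappings] == ["1:1", "1:1"]

    def test_fan_out_and_fan_in(self):
        # A:1 -> {B:1, B:2}; {A:1, A:2} -> B:2 — counts derived by hand
        out = compute_cardinality(
            ms([mapping("A:1", "skos:exactMatch", "B:1"),
                mapping("A:1", "skos:exactMatch", "B:2"),
                mapping("A:2", "skos:exactMatch", "B:2")])
        )
        assert [m.mapping_cardinality for m in out.mappings] == ["1:n", "n:n", "n:1"]

    def test_negated_rows_excluded(self):
        out = compute_cardinality(
            ms([mapping("A:1", "skos:exactMatch", "B:1"),
                mapping("A:1", "skos:exactMatch", "B:2", predicate_modifier="Not")])
        )
        assert out.mappings[0].mapping_cardinality == "1:1"
        assert out.mappings[1].mapping_cardinality is None


class TestReconcileUniqueObject:
    def test_higher_confidence_wins(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1", confidence=0.9),
            mapping("A:2", "skos:exactMatch", "B:1", confidence=0.8),
        ]
        accepted, rejected = reconcile_unique_object(ms(rows))
        assert [m.subject_id for m in accepted.mappings] == ["A:1"]
        assert [m.subject_id for m in rejected.mappings] == ["A:2"]
        assert rejected.mappings[0].predicate_modifier is PredicateModifier.Not
        assert "rejected" in rejected.mappings[0].comment

    def test_match_type_rank_breaks_confidence_tie(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1", match_type="Lexical", confidence=0.8),
            mapping("A:2", "skos:exactMatch", "B:1", match_type="HumanCurated", confidence=0.8),
        ]
        accepted, _ = reconcile_unique_object(ms(rows))
        exact = [m for m in accepted.mappings if m.object_id == "B:1"]
        assert [m.subject_id for m in exact] == ["A:2"]

    def test_subject_id_breaks_full_tie(self):
        rows = [
            mapping("A:2", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:exactMatch", "B:1"),
        ]
        accepted, _ = reconcile_unique_object(ms(rows))
        assert [m.subject_id for m in accepted.mappings] == ["A:1"]

    def test_single_row_untouched(self):
        rows = [mapping("A:1", "skos:exactMatch", "B:1")]
        accepted, rejected = reconcile_unique_object(ms(rows))
        assert accepted.mappings == rows and rejected.mappings == []

    def test_non_exact_rows_pass_through(self):
        rows = [
            mapping("A:1", "skos:relatedMatch", "B:1"),
            mapping("A:2", "skos:relatedMatch", "B:1"),
        ]
        accepted, rejected = reconcile_unique_object(ms(rows))
        assert len(accepted.mappings) == 2 and rejected.mappings == []

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_invariant(self, seed):
        from sssomkit.synthetic import random_mapping_set

        s = random_mapping_set(seed, n_rows_max=20)
        accepted, rejected = reconcile_unique_object(s)
        assert len(accepted.mappings) + len(rejected.mappings) == len(s.mappings)
        objects = [
            m.object_id
            for m in accepted.mappings
            if not m.is_negated() and predicate_class(m.predicate_id) is Strength.EXACT
        ]
        assert len(objects) == len(set(objects))
        assert all(m.is_negated() for m in rejected.mappings)


class TestDetectConflicts:
    def test_negation_clash(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:exactMatch", "B:1", predicate_modifier="Not"),
        ]
        reports = detect_conflicts(ms(rows))
        assert [r.kind for r in reports] == [ConflictKind.NEGATION_CLASH]
        assert reports[0].pair == ("A:1", "B:1") and reports[0].rows == (0, 1)

    def test_strength_clash(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:relatedMatch", "B:1"),
        ]
        reports = detect_conflicts(ms(rows))
        assert [r.kind for r in reports] == [ConflictKind.STRENGTH_CLASH]

    def test_conflict_free(self):
        rows = [
            mapping("A:1", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:closeMatch", "B:1"),  # CLOSE does not clash with EXACT
            mapping("A:2", "skos:exactMatch", "B:2"),
        ]
        assert detect_conflicts(ms(rows)) == []

    def test_sorted_by_pair(self):
        rows = [
            mapping("A:2", "skos:exactMatch", "B:2"),
            mapping("A:2", "skos:relatedMatch", "B:2"),
            mapping("A:1", "skos:exactMatch", "B:1"),
            mapping("A:1", "skos:exactMatch", "B:1", predicate_modifier="Not"),
        ]
        reports = detect_conflicts(ms(rows))
        assert [r.pair for r in reports] == [("A:1", "B:1"), ("A:2", "B:2")]
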