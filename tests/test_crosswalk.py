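"""Crosswalk traversal against an independent brute-force path oracle."""

import random
from itertools import permutations, product

import pytest

from sssomkit.crosswalk import COMPOSITION, build_graph, compose, neighbors
from sssomkit.curie import PrefixMap
from sssomkit.errors import SssomError
from sssomkit.model import MappingSet
from sssomkit.registry import Strength
from tests.conftest import mapping

S = Strength


# --------------------------------------------------------------------------
# independent oracle: rule-based composition + exhaustive path enumeration


def rule_compose(x, y):
    """Spec rules restated independently of the COMPOSITION dict."""
    if x is S.EXACT:
        return y
    if y is S.EXACT:
        return x
    if x is S.BROAD and y is S.BROAD:
        return S.BROAD
    if x is S.NARROW and y is S.NARROW:
        return S.NARROW
    if x is S.CLOSE and y is S.CLOSE:
        return S.RELATED
    return None


def rule_fold(path):
    result = path[0]
    for step in path[1:]:
        if result is None:
            return None
        result = rule_compose(result, step)
    return result


_RANK = {S.EXACT: 3, S.CLOSE: 2, S.RELATED: 1, S.BROAD: 0, S.NARROW: 0}
_INV = {S.EXACT: S.EXACT, S.CLOSE: S.CLOSE, S.RELATED: S.RELATED,
        S.BROAD: S.NARROW, S.NARROW: S.BROAD}


def oracle_neighbors(edges, start, max_distance):
    """Exhaustively enumerate simple paths via intermediate-node
    permutations; per entity keep min distance, then strongest strength."""
    directed = {}
    nodes = set()
    for a, b, s in edges:
        directed.setdefault((a, b), []).append(s)
        directed.setdefault((b, a), []).append(_INV[s])
        nodes.update((a, b))
    if start not in nodes:
        return {}
    others = sorted(nodes - {start})
    best = {}
    for target in others:
        for distance in range(1, max_distance + 1):
            found = None
            mids_pool = [n for n in others if n != target]
            for mids in permutations(mids_pool, distance - 1):
                hops = list(zip((start,) + mids, mids + (target,)))
                if not all(h in directed for h in hops):
                    continue
                for choice in product(*(directed[h] for h in hops)):
                    strength = rule_fold(choice)
                    if strength is None:
                        continue
                    if found is None or _RANK[strength] > _RANK[found]:
                        found = strength
            if found is not None:
                best[target] = (distance, found)
                break
    return best


def edges_to_set(edges):
    strength_to_predicate = {
        S.EXACT: "skos:exactMatch",
        S.CLOSE: "skos:closeMatch",
        S.RELATED: "skos:relatedMatch",
        S.BROAD: "skos:broadMatch",
        S.NARROW: "skos:narrowMatch",
    }
    pm = PrefixMap({"N": "https://example.org/n/"})
    return MappingSet(
        mapping_set_id="https://example.org/ms/graph",
        curie_map=pm,
        mappings=[mapping(a, strength_to_predicate[s], b) for a, b, s in edges],
    )


def random_edges(rng, n_nodes, n_edges):
    node_names = [f"N:{i}" for i in range(n_nodes)]
    strengths = [S.EXACT, S.CLOSE, S.RELATED, S.BROAD, S.NARROW]
    edges = []
    for _ in range(n_edges):
        a, b = rng.sample(node_names, 2)
        edges.append((a, b, rng.choice(strengths)))
    return edges


# --------------------------------------------------------------------------


class TestCompose:
    def test_brute_force_fold_agreement(self):
        strengths = [S.EXACT, S.CLOSE, S.RELATED, S.BROAD, S.NARROW]
        for length in (1, 2, 3):
            for path in product(strengths, repeat=length):
                assert compose(path) == rule_fold(path), path

    def test_exact_only_paths_stay_exact(self):
        for length in range(1, 6):
            assert compose((S.EXACT,) * length) is S.EXACT

    @pytest.mark.parametrize(
        "path,expected",
        [
            ((S.EXACT, S.EXACT), S.EXACT),
            ((S.EXACT, S.RELATED), S.RELATED),
            ((S.BROAD, S.NARROW), None),
            ((S.CLOSE, S.CLOSE), S.RELATED),
            ((S.CLOSE, S.CLOSE, S.CLOSE), None),
            ((S.RELATED, S.RELATED), None),
        ],
    )
    def test_table_entries(self, path, expected):
        assert compose(path) == expected

    def test_empty_path_is_usage_error(self):
        with pytest.raises(SssomError):
            compose(())


class TestBuildGraph:
    def test_filters(self):
        rows = [
            mapping("N:0", "skos:exactMatch", "N:1"),
            mapping("N:0", "skos:exactMatch", "N:2", predicate_modifier="Not"),
            mapping("N:0", "skos:exactMatch", "N:3", confidence=0.4),
            mapping("N:0", "N:customRelation", "N:4"),
            mapping("N:0", "skos:exactMatch", "N:5"),
        ]
        ms = MappingSet(
            mapping_set_id="https://example.org/ms/g",
            curie_map=PrefixMap({"N": "https://example.org/n/"}),
            mappings=rows,
        )
        graph = build_graph(ms, min_confidence=0.5, obsolete=["N:5"])
        reachable = {n.entity for n in neighbors(graph, "N:0", 1)}
        assert reachable == {"N:1"}

    def test_rows_without_confidence_pass_threshold(self):
        ms = edges_to_set([("N:0", "N:1", S.EXACT)])
        graph = build_graph(ms, min_confidence=0.99)
        assert [n.entity for n in neighbors(graph, "N:0", 1)] == ["N:1"]


class TestLimbFixture:
    def test_one_hop_single_exact_neighbor(self, limb_set):
        graph = build_graph(limb_set)
        found = neighbors(graph, "FMA:24875", 1)
        assert [(n.entity, n.strength, n.distance) for n in found] == [
            ("UBERON:0002101", S.EXACT, 1)
        ]

    def test_two_hops_min_strength_exact_excludes_related(self, limb_set):
        graph = build_graph(limb_set)
        found = neighbors(graph, "FMA:24875", 2, min_strength=S.EXACT)
        assert {n.entity for n in found} == {"UBERON:0002101", "MA:0000007"}

    def test_two_hops_unfiltered_reports_related(self, limb_set):
        graph = build_graph(limb_set)
        by_entity = {n.entity: n for n in neighbors(graph, "FMA:24875", 2)}
        assert by_entity["UMLS:C0015385"].strength is S.RELATED
        assert by_entity["UMLS:C0015385"].distance == 2

    def test_obsolete_terms_never_enter_graph(self, limb_set):
        limb_set.mappings.append(mapping("UBERON:0002101", "skos:exactMatch", "EFO:0000876"))
        graph = build_graph(limb_set, obsolete=["EFO:0000876"])
        assert "EFO:0000876" not in {n.entity for n in neighbors(graph, "FMA:24875", 2)}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs_agree_with_enumeration(self, seed):
        rng = random.Random(seed)
        edges = random_edges(rng, rng.randint(4, 9), rng.randint(3, 12))
        max_distance = rng.randint(1, 3)
        graph = build_graph(edges_to_set(edges))
        got = {n.entity: (n.distance, n.strength) for n in neighbors(graph, "N:0", max_distance)}
        expected = oracle_neighbors(edges, "N:0", max_distance)
        assert got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_distance(self, seed):
        rng = random.Random(1000 + seed)
        edges = random_edges(rng, rng.randint(4, 8), rng.randint(3, 10))
        graph = build_graph(edges_to_set(edges))
        near = {n.entity: n for n in neighbors(graph, "N:0", 2)}
        far = {n.entity: n for n in neighbors(graph, "N:0", 3)}
        for entity, info in near.items():
            assert entity in far
            if far[entity].distance == info.distance:
                assert _RANK[far[entity].strength] >= _RANK[info.strength]

    def test_start_not_in_graph_is_empty(self):
        graph = build_graph(edges_to_set([("N:0", "N:1", S.EXACT)]))
        assert neighbors(graph, "N:99", 2) == []

    def test_witness_paths_are_simple_and_valid(self):
        rng = random.Random(7)
        edges = random_edges(rng, 7, 10)
        graph = build_graph(edges_to_set(edges))
        for n in neighbors(graph, "N:0", 3):
            assert len(set(n.path)) == len(n.path)
            assert n.path[0] == "N:0" and n.path[-1] == n.entity
            assert len(n.path) - 1 == n.distance
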