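"""Tests of ORA, term similarities and redundancy reduction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylopace.pathways import (OntologyGraph, TermRecord, enrich_terms,
                                  jaccard_similarity, ora_hypergeometric,
                                  reduce_terms, wang_similarity)


def enumeration_ora_p(universe, term, query_size, k_obs):
    """Oracle: exhaustively enumerate all query subsets of the universe."""
    hits = total = 0
    for combo in itertools.combinations(sorted(universe), query_size):
        total += 1
        if len(set(combo) & set(term)) >= k_obs:
            hits += 1
    return hits / total


class TestORA:
    def test_saturated_query(self):
        uni = {f"g{i}" for i in range(10)}
        term = set(list(uni)[:4])
        assert ora_hypergeometric(uni, term, uni) == pytest.approx(1.0)

    def test_small_case_against_enumeration(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)*C(6,1)/C(10,5) = 6/252
        uni = [f"g{i}" for i in range(10)]
        term = set(uni[:4])
        query = set(uni[:4]) | {uni[9]}
        p = ora_hypergeometric(query, term, set(uni))
        assert p == pytest.approx(6 / 252, abs=1e-12)
        assert p == pytest.approx(
            enumeration_ora_p(uni, term, 5, 4), abs=1e-12)

    def test_zero_overlap_gives_one(self):
        uni = {f"g{i}" for i in range(12)}
        term = {"g0", "g1"}
        query = {"g10", "g11"}
        assert ora_hypergeometric(query, term, uni) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_small_universes_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(6, 13))
        uni = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        term = set(rng.choice(uni, K, replace=False))
        query = set(rng.choice(uni, n, replace=False))
        k = len(term & query)
        p = ora_hypergeometric(query, term, set(uni))
        assert p == pytest.approx(enumeration_ora_p(uni, term, n, k),
                                  abs=1e-10)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"g1"}, {"g1"})
        with pytest.raises(ValueError):
            ora_hypergeometric({"g1"}, {"g1"}, set())


class TestJaccard:
    def test_identity_disjoint_and_counts(self):
        assert jaccard_similarity({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_similarity({"a"}, {"b"}) == 0.0
        assert jaccard_similarity({"a", "b", "c"},
                                  {"b", "c", "d", "e"}) == pytest.approx(0.4)

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard_similarity(set(), set()) == 0.0


class TestWang:
    @staticmethod
    def _three_node_dag():
        return OntologyGraph([("A", "R", "is_a"), ("B", "R", "is_a")])

    def test_self_similarity_is_one(self):
        onto = self._three_node_dag()
        assert wang_similarity("A", "A", onto) == pytest.approx(1.0)

    def test_three_node_dag_value(self):
        # shared ancestor R with S=0.8 from both sides: (0.8+0.8)/(1.8+1.8)
        onto = self._three_node_dag()
        sim = wang_similarity("A", "B", onto)
        assert sim == pytest.approx(4 / 9, abs=1e-12)
        assert sim == pytest.approx(wang_similarity("B", "A", onto))

    def test_part_of_weight(self):
        onto = OntologyGraph([("A", "R", "is_a"), ("B", "R", "part_of")])
        sim = wang_similarity("A", "B", onto)
        # S_A(R)=0.8, S_B(R)=0.6 -> (0.8+0.6)/(1.8+1.6)
        assert sim == pytest.approx(1.4 / 3.4, abs=1e-12)

    def test_disconnected_components(self):
        onto = OntologyGraph([("A", "R1", "is_a"), ("B", "R2", "is_a")])
        assert wang_similarity("A", "B", onto) == 0.0

    def test_max_over_paths(self):
        # two routes from A to R: direct is_a (0.8) vs via M part_of
        onto = OntologyGraph([("A", "R", "is_a"), ("A", "M", "part_of"),
                              ("M", "R", "part_of")])
        sa = wang_similarity("A", "A", onto)
        assert sa == pytest.approx(1.0, abs=1e-12)
        onto2 = OntologyGraph([("A", "M", "is_a"), ("M", "R", "is_a"),
                               ("A", "R", "is_a")])
        # S_A(R) = max(0.8 direct, 0.8*0.8 via M) = 0.8
        sim = wang_similarity("A", "R", onto2)
        # T_A={A,M,R}, S_A = 1,0.8,0.8 ; T_R={R}, S_R(R)=1
        assert sim == pytest.approx((0.8 + 1.0) / (2.6 + 1.0), abs=1e-12)

    def test_errors(self):
        onto = self._three_node_dag()
        with pytest.raises(KeyError):
            wang_similarity("A", "missing", onto)
        with pytest.raises(ValueError, match="cycle"):
            OntologyGraph([("A", "B", "is_a"), ("B", "A", "is_a")])
        with pytest.raises(ValueError, match="relation"):
            OntologyGraph([("A", "B", "regulates")])


def _term(term, genes, adj_p, source="KEGG"):
    return TermRecord(term=term, source=source, genes=frozenset(genes),
                      raw_p=adj_p / 2, adj_p=adj_p)


class TestReduceTerms:
    def test_no_edges_everyone_representative(self):
        terms = [_term(f"T{i}", {f"g{i}a", f"g{i}b"}, 0.01 * (i + 1))
                 for i in range(5)]
        graph = reduce_terms(terms, threshold=0.5)
        assert len(graph.representatives) == 5
        assert len(set(graph.communities.values())) == 5

    def test_duplicate_gene_sets_collapse_to_best_p(self):
        terms = [_term("T1", {"a", "b", "c"}, 0.01),
                 _term("T2", {"a", "b", "c"}, 0.03)]
        graph = reduce_terms(terms)
        assert graph.representatives == ["T1"]

    def test_nine_term_two_cliques_plus_isolate(self):
        """Two 4-term cliques (within-clique Jaccard > 0.5, between < 0.5)
        plus one isolate give exactly 3 representatives, matching the
        brute-force connected-component count."""
        import networkx as nx
        base1 = {f"a{i}" for i in range(10)}
        base2 = {f"b{i}" for i in range(10)}
        terms = []
        for i in range(4):
            terms.append(_term(f"A{i}", base1 | {f"xa{i}"}, 0.01 * (i + 1)))
            terms.append(_term(f"B{i}", base2 | {f"xb{i}"}, 0.02 * (i + 1)))
        terms.append(_term("LONER", {f"z{i}" for i in range(10)}, 0.5))
        graph = reduce_terms(terms, threshold=0.5)
        # oracle: connected components of the explicit similarity graph
        g = nx.Graph()
        g.add_nodes_from(t.term for t in terms)
        for t1, t2 in itertools.combinations(terms, 2):
            if jaccard_similarity(t1.genes, t2.genes) > 0.5:
                g.add_edge(t1.term, t2.term)
        assert len(graph.representatives) == nx.number_connected_components(g)
        assert set(graph.representatives) == {"A0", "B0", "LONER"}

    def test_threshold_is_strict(self):
        # Jaccard exactly 0.5 must NOT create an edge
        terms = [_term("T1", {"a", "b"}, 0.01),
                 _term("T2", {"a", "c"}, 0.02),     # Jaccard 1/3
                 _term("T3", {"a", "b", "c", "d"}, 0.03)]  # with T1: 2/4
        graph = reduce_terms(terms, threshold=0.5)
        assert len(graph.representatives) == 3

    def test_input_order_invariance(self, rng):
        terms = [_term(f"T{i}", set(rng.choice([f"g{j}" for j in range(15)],
                                               8, replace=False)),
                       float(rng.uniform(0.001, 0.2)))
                 for i in range(12)]
        fwd = reduce_terms(terms)
        rev = reduce_terms(terms[::-1])
        assert fwd.representatives == rev.representatives
        assert fwd.communities == rev.communities

    def test_sources_never_mix(self):
        shared = {f"g{i}" for i in range(10)}
        terms = [_term("K1", shared, 0.01, source="KEGG"),
                 _term("R1", shared, 0.02, source="Reactome")]
        graph = reduce_terms(terms)
        assert len(graph.representatives) == 2
        assert graph.edges == []

    def test_go_without_ontology_raises(self):
        terms = [_term("GO:1", {"a"}, 0.01, source="GO")]
        with pytest.raises(ValueError, match="ontology"):
            reduce_terms(terms)
        # the instructed fallback works
        graph = reduce_terms(terms, jaccard_fallback=True)
        assert graph.representatives == ["GO:1"]

    def test_wang_based_go_reduction(self):
        onto = OntologyGraph([("GO:A", "GO:R", "is_a"),
                              ("GO:B", "GO:A", "is_a"),
                              ("GO:C", "GO:R", "is_a")])
        terms = [_term("GO:A", {"x"}, 0.01, source="GO"),
                 _term("GO:B", {"y"}, 0.02, source="GO"),
                 _term("GO:C", {"z"}, 0.03, source="GO")]
        graph = reduce_terms(terms, ontology=onto)
        # B is_a A: sim(A,B) = (1.8+1.8*0.8)/(1.8+2.44) ~ 0.76 -> merged
        assert wang_similarity("GO:A", "GO:B", onto) > 0.5
        assert "GO:A" in graph.representatives
        assert graph.communities["GO:A"] == graph.communities["GO:B"]


def test_enrich_terms_bh_within_source(rng):
    genes = [f"g{i}" for i in range(60)]
    sets = {f"T{i}": set(rng.choice(genes, 12, replace=False))
            for i in range(8)}
    query = set(rng.choice(genes, 15, replace=False))
    records = enrich_terms(query, sets, set(genes), source="KEGG")
    assert all(r.adj_p >= r.raw_p - 1e-15 for r in records)
    frame = pd.DataFrame([(r.raw_p, r.adj_p) for r in records],
                         columns=["raw", "adj"]).sort_values("raw")
    assert np.all(np.diff(frame["adj"]) >= -1e-12)
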