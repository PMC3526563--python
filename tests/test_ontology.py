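"""Ontology parsing and Wang semantic similarity."""

import math

import networkx as nx
import numpy as np
import pytest

from goqa.ontology import (
    DEFAULT_WEIGHTS,
    GODag,
    GOTerm,
    ObsoleteTermError,
    OntologyError,
    SemanticWeights,
    UnknownTermError,
    functional_similarity,
    parse_obo,
    s_values,
    term_similarity,
    write_obo,
)
from goqa.synthetic import generate_toy_dag

A, B, ROOT = "GO:0000003", "GO:0000002", "GO:0000001"


def brute_force_s_values(dag, term, weights=DEFAULT_WEIGHTS):
    """Independent oracle: maximise the edge-weight product over every
    directed path from the query term to each ancestor."""
    sub = dag.ancestor_subgraph(term)
    out = {}
    for node in sub.nodes:
        if node == term:
            out[node] = 1.0
            continue
        best = 0.0
        for path in nx.all_simple_edge_paths(sub, term, node):
            product = 1.0
            for _, _, relation in path:
                product *= weights.for_relation(relation)
            best = max(best, product)
        out[node] = best
    return out


class TestParseObo:
    def test_minimal_document(self):
        dag = parse_obo(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: r\n"
            "namespace: molecular_function\n\n[Term]\nid: GO:0000002\nname: a\n"
            "namespace: molecular_function\nis_a: GO:0000001\n"
        )
        assert len(dag) == 2
        assert dag["GO:0000002"].parents == (("GO:0000001", "is_a"),)

    def test_obsolete_term_flagged_and_parentless(self):
        dag = parse_obo(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: r\n"
            "namespace: molecular_function\n\n[Term]\nid: GO:0000002\nname: o\n"
            "namespace: molecular_function\nis_a: GO:0000001\nis_obsolete: true\n"
        )
        term = dag["GO:0000002"]
        assert term.obsolete and term.parents == ()
        with pytest.raises(ObsoleteTermError):
            s_values(dag, "GO:0000002")

    def test_non_semantic_relationship_dropped_and_counted(self):
        dag = parse_obo(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: r\n"
            "namespace: molecular_function\n\n[Term]\nid: GO:0000002\nname: a\n"
            "namespace: molecular_function\nis_a: GO:0000001\n"
            "relationship: regulates GO:0000001\n"
        )
        assert dag.dropped_relationships == 1
        assert dag["GO:0000002"].parents == (("GO:0000001", "is_a"),)

    def test_alt_id_resolves_to_primary(self, chain_dag):
        dag = parse_obo(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: r\n"
            "namespace: molecular_function\nalt_id: GO:0000099\n"
        )
        assert dag.resolve("GO:0000099") == "GO:0000001"
        with pytest.raises(UnknownTermError):
            dag.resolve("GO:1234567")

    def test_dangling_parent_is_load_error(self):
        with pytest.raises(OntologyError, match="dangling"):
            parse_obo(
                "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: a\n"
                "namespace: molecular_function\nis_a: GO:0009999\n"
            )

    def test_cycle_is_load_error_naming_the_cycle(self):
        terms = {
            "GO:0000001": GOTerm("GO:0000001", "a", "molecular_function",
                                 parents=(("GO:0000002", "is_a"),)),
            "GO:0000002": GOTerm("GO:0000002", "b", "molecular_function",
                                 parents=(("GO:0000001", "is_a"),)),
        }
        with pytest.raises(OntologyError, match="cycle.*GO:000000"):
            GODag(terms)

    def test_obo_round_trip(self, tmp_path, diamond_dag):
        path = tmp_path / "toy.obo"
        with open(path, "w") as fh:
            write_obo(diamond_dag, fh)
        reparsed = parse_obo(str(path))
        assert set(reparsed.terms) == set(diamond_dag.terms)
        for tid in diamond_dag.terms:
            assert sorted(reparsed[tid].parents) == sorted(diamond_dag[tid].parents)


class TestAncestors:
    def test_chain(self, chain_dag):
        assert chain_dag.ancestors(A) == {A, B, ROOT}

    def test_root_is_its_own_subgraph(self, chain_dag):
        assert chain_dag.ancestors(ROOT) == {ROOT}

    def test_diamond_nodes_and_edges(self, diamond_dag):
        sub = diamond_dag.ancestor_subgraph("GO:0000004")
        assert set(sub.nodes) == set(diamond_dag.terms)
        assert sub.number_of_edges() == 4


class TestSValues:
    def test_chain_hand_values(self, chain_dag):
        sv = s_values(chain_dag, A)
        assert sv.svalues == pytest.approx({A: 1.0, B: 0.8, ROOT: 0.64})
        assert sv.sv_total == pytest.approx(2.44)

    def test_single_root(self, chain_dag):
        sv = s_values(chain_dag, ROOT)
        assert sv.svalues == {ROOT: 1.0} and sv.sv_total == 1.0

    def test_diamond_takes_best_path(self, diamond_dag):
        sv = s_values(diamond_dag, "GO:0000004")
        # paths to root: is_a/is_a (0.64) vs is_a/part_of (0.48)
        assert sv.svalues["GO:0000001"] == pytest.approx(0.64)
        assert sv.svalues == pytest.approx(
            brute_force_s_values(diamond_dag, "GO:0000004")
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        dag = generate_toy_dag(int(rng.integers(2, 31)),
                               p_part_of=float(rng.uniform(0, 0.5)),
                               max_parents=3, seed=seed)
        term = sorted(dag.terms)[int(rng.integers(len(dag)))]
        got = s_values(dag, term).svalues
        expected = brute_force_s_values(dag, term)
        assert got == pytest.approx(expected, abs=1e-12)


class TestTermSimilarity:
    def test_self_similarity_is_one(self, chain_dag):
        for term in chain_dag.terms:
            assert term_similarity(chain_dag, term, term) == pytest.approx(1.0)

    def test_siblings_hand_value(self, siblings_dag):
        assert term_similarity(siblings_dag, "GO:0000002", "GO:0000003") == \
            pytest.approx(0.4444, abs=5e-5)

    def test_chain_hand_value(self, chain_dag):
        assert term_similarity(chain_dag, A, B) == pytest.approx(0.7642, abs=5e-5)

    def test_cross_namespace_is_error(self):
        terms = {
            "GO:0000001": GOTerm("GO:0000001", "f", "molecular_function"),
            "GO:0000002": GOTerm("GO:0000002", "p", "biological_process"),
        }
        dag = GODag(terms)
        with pytest.raises(ValueError, match="cross-namespace"):
            term_similarity(dag, "GO:0000001", "GO:0000002")

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_range_on_random_dags(self, seed):
        dag = generate_toy_dag(20, seed=seed)
        rng = np.random.default_rng(seed)
        ids = sorted(dag.terms)
        for _ in range(50):
            a, b = (ids[int(i)] for i in rng.integers(len(ids), size=2))
            sab = term_similarity(dag, a, b)
            assert sab == term_similarity(dag, b, a)
            assert 0.0 <= sab <= 1.0


class TestFunctionalSimilarity:
    def test_identical_sets_score_one(self, siblings_dag):
        assert functional_similarity(
            siblings_dag, ["GO:0000002", "GO:0000003"], ["GO:0000003", "GO:0000002"]
        ) == pytest.approx(1.0)

    def test_singletons_reduce_to_term_similarity(self, siblings_dag):
        assert functional_similarity(siblings_dag, ["GO:0000002"], ["GO:0000003"]) == \
            pytest.approx(term_similarity(siblings_dag, "GO:0000002", "GO:0000003"))

    def test_best_match_average_hand_value(self, siblings_dag):
        # {A, B} vs {B}: (Sim(A,B) + 1 + 1) / 3
        assert functional_similarity(
            siblings_dag, ["GO:0000002", "GO:0000003"], ["GO:0000003"]
        ) == pytest.approx(0.8148, abs=5e-5)

    def test_empty_set_is_error(self, siblings_dag):
        with pytest.raises(ValueError):
            functional_similarity(siblings_dag, [], ["GO:0000002"])

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_on_random_sets(self, seed):
        dag = generate_toy_dag(25, seed=seed)
        rng = np.random.default_rng(seed + 100)
        ids = sorted(dag.terms)
        for _ in range(20):
            s1 = [ids[int(i)] for i in rng.integers(len(ids), size=int(rng.integers(1, 4)))]
            s2 = [ids[int(i)] for i in rng.integers(len(ids), size=int(rng.integers(1, 4)))]
            fwd = functional_similarity(dag, s1, s2)
            assert fwd == functional_similarity(dag, s2, s1)
            assert 0.0 <= fwd <= 1.0


def test_weights_must_lie_strictly_inside_unit_interval():
    with pytest.raises(ValueError):
        SemanticWeights(w_is_a=1.0)
    with pytest.raises(ValueError):
        SemanticWeights(w_part_of=0.0)
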