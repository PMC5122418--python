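"""Structural IC, Lin/MICA and BMA similarity."""

import math

import numpy as np
import pytest

from mirlink.ontology import (
    OntologyError,
    bma_score_from_matrix,
    bma_similarity,
    information_content,
    lin_similarity,
    load_obo,
    mica,
)
from mirlink.synthetic import dag_to_obo, make_dag

from conftest import dag_from_edges
from oracles import brute_force_mica_ic, naive_bma

CHAIN_OBO = """format-version: 1.2

[Term]
id: T:1
name: one
namespace: biological_process

[Term]
id: T:2
name: two
namespace: biological_process
is_a: T:1

[Term]
id: T:3
name: three
namespace: biological_process
is_a: T:2

[Term]
id: T:4
name: four
namespace: biological_process
is_a: T:3

[Term]
id: T:5
name: five
namespace: biological_process
is_a: T:4
"""


class TestLoadObo:
    def test_chain_fixture_parses_to_five_terms_four_edges(self, tmp_path):
        path = tmp_path / "chain.obo"
        path.write_text(CHAIN_OBO)
        dag = load_obo(path)
        assert len(dag) == 5
        assert dag.graph.number_of_edges() == 4
        assert dag.root == "T:1"

    def test_obsolete_terms_are_dropped(self, tmp_path):
        path = tmp_path / "obs.obo"
        path.write_text(
            CHAIN_OBO
            + "\n[Term]\nid: T:6\nname: gone\nnamespace: biological_process\n"
            "is_a: T:1\nis_obsolete: true\n"
        )
        dag = load_obo(path)
        assert "T:6" not in dag

    def test_cycle_is_a_hard_error_naming_an_edge(self, tmp_path):
        path = tmp_path / "cyc.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: a\nnamespace: biological_process\nis_a: b\n\n"
            "[Term]\nid: b\nnamespace: biological_process\nis_a: a\n"
        )
        with pytest.raises(OntologyError, match="cyclic"):
            load_obo(path)

    def test_missing_namespace_is_an_error(self, tmp_path):
        path = tmp_path / "chain.obo"
        path.write_text(CHAIN_OBO)
        with pytest.raises(OntologyError, match="namespace"):
            load_obo(path, namespace="molecular_function")


class TestInformationContent:
    def test_seven_term_hand_values(self, seven_term_dag, seven_term_ic):
        ic = seven_term_ic
        assert ic["root"].n_t == 7
        assert ic["root"].p_t == 1.0
        assert ic["root"].ic == 0.0
        assert ic["A1"].n_t == 1
        assert ic["A1"].p_t == pytest.approx(1 / 7)
        assert ic["A1"].ic == pytest.approx(-math.log(1 / 7), abs=1e-12)
        assert ic["A1"].ic == pytest.approx(1.9459, abs=1e-4)
        # A has two leaf children: itself + 2 descendants
        assert ic["A"].n_t == 3
        assert ic["A"].p_t == pytest.approx(3 / 7)

    def test_ic_monotone_along_every_edge(self):
        dag = make_dag(50, seed=11)
        ic = information_content(dag)
        for child, parent in dag.graph.edges:
            assert ic[child].ic >= ic[parent].ic

    def test_multiple_inheritance_counts_distinct_descendants_once(self):
        # diamond: d is_a b, d is_a c, b/c is_a a
        dag = dag_from_edges([("b", "a"), ("c", "a"), ("d", "b"), ("d", "c")])
        ic = information_content(dag)
        assert ic["a"].n_t == 4  # d counted once despite two paths


class TestLinSimilarity:
    def test_self_similarity_of_non_root_is_one(self, seven_term_dag, seven_term_ic):
        assert lin_similarity("A1", "A1", seven_term_ic, seven_term_dag) == 1.0

    def test_only_common_ancestor_root_gives_zero(self, seven_term_dag, seven_term_ic):
        assert lin_similarity("A1", "B1", seven_term_ic, seven_term_dag) == 0.0

    def test_sibling_leaves_hand_value(self, seven_term_dag, seven_term_ic):
        expected = 2 * math.log(7 / 3) / (2 * math.log(7))
        got = lin_similarity("A1", "A2", seven_term_ic, seven_term_dag)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_root_pair_conventions(self, seven_term_dag, seven_term_ic):
        assert lin_similarity("root", "root", seven_term_ic, seven_term_dag) == 1.0
        assert lin_similarity("root", "A", seven_term_ic, seven_term_dag) == 0.0

    def test_absent_term_raises(self, seven_term_dag, seven_term_ic):
        with pytest.raises(KeyError):
            lin_similarity("A1", "nope", seven_term_ic, seven_term_dag)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_mica_on_random_dags(self, seed):
        dag = make_dag(50, branching=3, seed=seed)
        ic = information_content(dag)
        parents = {t: dag.parents(t) for t in dag.terms}
        ic_plain = {t: v.ic for t, v in ic.items()}
        rng = np.random.default_rng(seed)
        terms = sorted(dag.terms)
        for _ in range(50):
            t1, t2 = (terms[i] for i in rng.integers(len(terms), size=2))
            got = lin_similarity(t1, t2, ic, dag)
            assert 0.0 <= got <= 1.0
            denom = ic_plain[t1] + ic_plain[t2]
            expected = (
                1.0 if t1 == t2 and denom == 0
                else 0.0 if denom == 0
                else 2 * brute_force_mica_ic(t1, t2, parents, ic_plain) / denom
            )
            assert got == pytest.approx(expected, abs=1e-12)

    def test_mica_tie_break_is_lexicographic(self, seven_term_dag, seven_term_ic):
        assert mica("A1", "A2", seven_term_ic, seven_term_dag) == "A"


class TestBmaSimilarity:
    def test_hand_matrix_score(self):
        matrix = np.array([[1.0, 0.2], [0.4, 0.6]])
        # (1.0 + 0.6 + 1.0 + 0.6) / 4
        assert bma_score_from_matrix(matrix) == pytest.approx(0.8)

    def test_identical_sets_score_one(self, seven_term_dag, seven_term_ic):
        s = {"A1", "A2", "B1"}
        result = bma_similarity(s, s, seven_term_ic, seven_term_dag)
        assert result.score == pytest.approx(1.0)

    def test_symmetric_under_set_swap(self, seven_term_dag, seven_term_ic):
        s1, s2 = {"A1", "B1"}, {"A2", "B2", "A"}
        r12 = bma_similarity(s1, s2, seven_term_ic, seven_term_dag)
        r21 = bma_similarity(s2, s1, seven_term_ic, seven_term_dag)
        assert r12.score == pytest.approx(r21.score, abs=1e-15)

    def test_empty_set_is_an_error(self, seven_term_dag, seven_term_ic):
        with pytest.raises(ValueError):
            bma_similarity(set(), {"A1"}, seven_term_ic, seven_term_dag)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_naive_double_loop_on_random_term_sets(self, seed):
        dag = make_dag(40, seed=seed)
        ic = information_content(dag)
        rng = np.random.default_rng(seed)
        terms = sorted(dag.terms)
        s1 = {terms[i] for i in rng.choice(len(terms), 6, replace=False)}
        s2 = {terms[i] for i in rng.choice(len(terms), 4, replace=False)}
        result = bma_similarity(s1, s2, ic, dag)
        assert result.score == pytest.approx(naive_bma(result.pair_matrix), abs=1e-12)

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(3)
        matrix = rng.random((5, 7))
        permuted = matrix[rng.permutation(5)][:, rng.permutation(7)]
        assert bma_score_from_matrix(matrix) == pytest.approx(
            bma_score_from_matrix(permuted)
        )
        assert bma_score_from_matrix(matrix) == pytest.approx(naive_bma(matrix))


def test_obo_round_trip_preserves_structure():
    dag = make_dag(25, seed=4)
    text = dag_to_obo(dag)
    import pathlib
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "synthetic.obo"
        path.write_text(text)
        dag2 = load_obo(path)
    assert dag2.terms == dag.terms
    assert set(dag2.graph.edges) == set(dag.graph.edges)
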