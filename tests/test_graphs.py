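import itertools

import numpy as np
import pytest

from copulacd import (DAG, Mark, PAG, d_separated, enumerate_dags,
                      evaluate_pag, ground_truth_pag, pag_accuracy,
                      skeleton_precision_recall)
from copulacd.graphs import MAX_ENUM_NODES

from _oracles import brute_force_dags, dsep_paths, pag_by_mag_enumeration
from conftest import BENCHMARK_DAGS


class TestDAG:
    def test_rejects_cycles_self_loops_unknown_nodes(self):
        with pytest.raises(ValueError, match="cycle"):
            DAG("AB", [("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="self-loop"):
            DAG("AB", [("A", "A")])
        with pytest.raises(ValueError, match="unknown"):
            DAG("AB", [("A", "C")])

    def test_ancestor_and_v_structure_queries(self):
        dag = DAG("ABCD", [("A", "B"), ("B", "C"), ("D", "C")])
        assert dag.ancestors("C") == {"A", "B", "D"}
        assert dag.is_ancestor("A", "C") and not dag.is_ancestor("C", "A")
        assert dag.v_structures() == {("B", "C", "D")}


class TestEnumeration:
    @pytest.mark.parametrize("n, expected", [(1, 1), (2, 3), (3, 25),
                                             (4, 543), (5, 29281)])
    def test_labeled_dag_counts(self, n, expected):
        nodes = tuple(f"V{i}" for i in range(n))
        dags = enumerate_dags(nodes)
        assert len(dags) == expected
        assert len({d.edges for d in dags}) == expected  # no duplicates

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_brute_force_digraph_filter(self, n):
        nodes = tuple("WXYZ"[:n])
        ours = {d.edges for d in enumerate_dags(nodes)}
        brute = set(brute_force_dags(nodes))
        assert ours == brute

    def test_refuses_large_node_sets_without_override(self):
        with pytest.raises(ValueError, match="refused"):
            enumerate_dags(tuple("ABCDEF"))
        assert MAX_ENUM_NODES == 5


class TestDSeparation:
    def test_textbook_cases(self):
        chain = DAG("ABC", [("A", "B"), ("B", "C")])
        collider = DAG("ABC", [("A", "B"), ("C", "B")])
        assert d_separated(chain, "A", "C", {"B"})
        assert d_separated(collider, "A", "C")
        assert not d_separated(collider, "A", "C", {"B"})
        # conditioning on a collider's descendant also opens the path
        desc = DAG("ABCD", [("A", "B"), ("C", "B"), ("B", "D")])
        assert not d_separated(desc, "A", "C", {"D"})

    def test_input_validation(self):
        dag = DAG("AB", [("A", "B")])
        with pytest.raises(ValueError, match="unknown"):
            d_separated(dag, "A", "Q")
        with pytest.raises(ValueError):
            d_separated(dag, "A", "A")
        with pytest.raises(ValueError):
            d_separated(dag, "A", "B", {"A"})

    def test_bitmask_variant_agrees_with_reference_exhaustively(self):
        """The Bayes-ball bitmask d-separation that powers the scoring hot
        path agrees with the name-based implementation on every 4-node DAG,
        pair and conditioning set."""
        from copulacd.graphs import dseparated_mask

        nodes = tuple("WXYZ")
        for dag in enumerate_dags(nodes):
            pmask = [0] * 4
            for a, b in dag.edges:
                pmask[nodes.index(b)] |= 1 << nodes.index(a)
            for i, j in itertools.combinations(range(4), 2):
                others = [k for k in range(4) if k not in (i, j)]
                for r in range(3):
                    for zs in itertools.combinations(others, r):
                        zmask = sum(1 << k for k in zs)
                        expect = d_separated(dag, nodes[i], nodes[j],
                                             {nodes[k] for k in zs})
                        assert dseparated_mask(pmask, i, j, zmask) == expect

    @pytest.mark.parametrize("n", [3, 4])
    def test_agrees_with_path_enumeration_oracle_exhaustively(self, n):
        nodes = tuple("WXYZ"[:n])
        for dag in enumerate_dags(nodes):
            for x, y in itertools.combinations(nodes, 2):
                others = [v for v in nodes if v not in (x, y)]
                for k in range(len(others) + 1):
                    for zs in itertools.combinations(others, k):
                        assert d_separated(dag, x, y, set(zs)) == \
                            dsep_paths(dag, x, y, set(zs))


class TestGroundTruthPAG:
    def test_single_edge_is_unorientable(self):
        pag = ground_truth_pag(DAG("AB", [("A", "B")]))
        assert pag.mark("A", "B") is Mark.CIRCLE
        assert pag.mark("B", "A") is Mark.CIRCLE

    def test_collider_gets_arrowheads_circled_tails(self):
        pag = ground_truth_pag(DAG("ABC", [("A", "B"), ("C", "B")]))
        assert pag.mark("A", "B") is Mark.ARROW
        assert pag.mark("C", "B") is Mark.ARROW
        assert pag.mark("B", "A") is Mark.CIRCLE
        assert pag.mark("B", "C") is Mark.CIRCLE
        assert not pag.has_edge("A", "C")

    @pytest.mark.parametrize("name", ["chain3", "collider3", "fork3",
                                      "chain4", "diamond4", "collider4"])
    def test_matches_mag_enumeration_oracle(self, name):
        nodes, edges = BENCHMARK_DAGS[name]
        dag = DAG(tuple(nodes), edges)
        assert ground_truth_pag(dag) == pag_by_mag_enumeration(dag)

    def test_latent_confounder_yields_unshielded_collider(self):
        # L is a hidden common cause of B and C; A -> B is observed
        dag = DAG(("L", "A", "B", "C"),
                  [("L", "B"), ("L", "C"), ("A", "B")])
        pag = ground_truth_pag(dag, latent={"L"})
        assert pag.edges() == {frozenset(("A", "B")), frozenset(("B", "C"))}
        # A and C are marginally independent, so B is an unshielded collider
        assert pag.mark("A", "B") is Mark.ARROW
        assert pag.mark("C", "B") is Mark.ARROW

    def test_skeleton_and_v_structures_preserved_without_latents(self, rng):
        nodes = tuple("ABCDE")
        for _ in range(8):
            edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4]
            dag = DAG(nodes, edges)
            pag = ground_truth_pag(dag)
            assert pag.edges() == dag.skeleton()
            pag_colliders = set()
            for y in nodes:
                adj = sorted(pag.adjacent(y))
                for x, z in itertools.combinations(adj, 2):
                    if pag.has_edge(x, z):
                        continue
                    if pag.mark(x, y) is Mark.ARROW and \
                            pag.mark(z, y) is Mark.ARROW:
                        pag_colliders.add((x, y, z))
            assert pag_colliders == dag.v_structures()

    def test_rejects_bad_latent_sets(self):
        dag = DAG("AB", [("A", "B")])
        with pytest.raises(ValueError):
            ground_truth_pag(dag, latent={"Q"})
        with pytest.raises(ValueError):
            ground_truth_pag(dag, latent={"A", "B"})


class TestMetrics:
    def _pag(self, nodes, edges):
        pag = PAG(nodes)
        for x, y, mx, my in edges:
            pag.add_edge(x, y, mx, my)
        return pag

    def test_identity_and_symmetry(self):
        truth = ground_truth_pag(DAG("ABC", [("A", "B"), ("C", "B")]))
        assert pag_accuracy(truth, truth) == 1.0
        other = self._pag("ABC", [("A", "B", Mark.TAIL, Mark.ARROW)])
        assert pag_accuracy(other, truth) == pag_accuracy(truth, other)
        assert pag_accuracy(other, truth) < 1.0

    def test_empty_estimate_scores_zero_accuracy_full_precision(self):
        truth = self._pag("ABC", [("A", "B", Mark.TAIL, Mark.ARROW),
                                  ("B", "C", Mark.TAIL, Mark.ARROW)])
        empty = self._pag("ABC", [])
        assert pag_accuracy(empty, truth) == 0.0
        assert skeleton_precision_recall(empty, truth) == (1.0, 0.0)

    def test_all_circle_skeleton_scores_zero_marks_full_skeleton(self):
        truth = self._pag("ABC", [("A", "B", Mark.TAIL, Mark.TAIL),
                                  ("B", "C", Mark.TAIL, Mark.TAIL)])
        circles = self._pag("ABC", [("A", "B", Mark.CIRCLE, Mark.CIRCLE),
                                    ("B", "C", Mark.CIRCLE, Mark.CIRCLE)])
        assert pag_accuracy(circles, truth) == 0.0
        assert skeleton_precision_recall(circles, truth) == (1.0, 1.0)

    def test_counted_precision_recall(self):
        nodes = tuple("ABCDEFGH")
        true_edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
                      ("E", "F"), ("F", "G"), ("G", "H"), ("A", "H"),
                      ("B", "H"), ("C", "H")]
        truth = self._pag(nodes, [(a, b, Mark.CIRCLE, Mark.CIRCLE)
                                  for a, b in true_edges])
        est_edges = true_edges[:4] + [("A", "E")]  # 4 true + 1 false of 5
        est = self._pag(nodes, [(a, b, Mark.CIRCLE, Mark.CIRCLE)
                                for a, b in est_edges])
        assert skeleton_precision_recall(est, truth) == (0.8, 0.4)

    def test_node_set_mismatch_raises(self):
        a = self._pag("AB", [])
        b = self._pag("AC", [])
        with pytest.raises(ValueError):
            pag_accuracy(a, b)
        with pytest.raises(ValueError):
            skeleton_precision_recall(a, b)

    def test_evaluation_result_bounds(self):
        with pytest.raises(ValueError):
            from copulacd import EvaluationResult
            EvaluationResult(1.2, 0.5, 0.5)
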