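import itertools

import numpy as np
import pandas as pd
import pytest

from copulacd import (BackgroundKnowledge, CausalStatement, CorrelationMatrix,
                      DAG, Mark, MixedDataset, ReliabilityTable, bic_score,
                      d_separated, enumerate_dags, mutual_information,
                      orient_edges, run_bccd, score_subset,
                      statement_reliability)
from copulacd.bccd import adjacency_search, causal_reliabilities

from conftest import BENCHMARK_DAGS, linear_sem_correlation


def corr2(rho, m=100):
    return CorrelationMatrix([[1, rho], [rho, 1]], ("X", "Y"), m)


class TestMutualInformation:
    def test_empty_parent_set_is_zero(self):
        assert mutual_information(corr2(0.9), "X", []) == 0.0

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.5, 0.9, -0.7])
    def test_single_parent_closed_form(self, rho):
        got = mutual_information(corr2(rho), "X", ["Y"])
        assert got == pytest.approx(-0.5 * np.log(1 - rho ** 2), abs=1e-10)

    def test_two_independent_parents_determinant_oracle(self):
        r1, r2 = 0.4, 0.3
        R = np.array([[1, r1, r2], [r1, 1, 0], [r2, 0, 1]])
        corr = CorrelationMatrix(R, ("i", "p1", "p2"), 100)
        got = mutual_information(corr, "i", ["p1", "p2"])
        # 3x3 determinant expansion: det = 1 - r1^2 - r2^2
        assert got == pytest.approx(-0.5 * np.log(1 - r1 ** 2 - r2 ** 2),
                                    abs=1e-12)

    def test_singular_parent_matrix_advises_projection(self):
        R = np.array([[1, 0.5, 0.5], [0.5, 1, 1.0], [0.5, 1.0, 1]])
        corr = CorrelationMatrix(R, ("i", "p1", "p2"), 100)
        with pytest.raises(np.linalg.LinAlgError, match="positive-definite"):
            mutual_information(corr, "i", ["p1", "p2"])


class TestBICScore:
    def test_empty_dag_scores_zero(self):
        dag = DAG(("X", "Y"))
        assert bic_score(corr2(0.77), dag, 500) == 0.0

    def test_two_variable_worked_example(self):
        dag = DAG(("X", "Y"), [("X", "Y")])
        got = bic_score(corr2(0.5, 100), dag, 100)
        expected = 100 * 0.14384103622589045 - np.log(100) / 2
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(12.081, abs=1e-3)

    def test_direction_reversal_gives_identical_score(self):
        a = bic_score(corr2(0.62), DAG("XY", [("X", "Y")]), 321)
        b = bic_score(corr2(0.62), DAG("XY", [("Y", "X")]), 321)
        assert a == pytest.approx(b, rel=1e-12)

    def test_markov_equivalent_dags_score_identically_exhaustively(self, rng):
        """Score equivalence on every pair of Markov-equivalent 3-node DAGs."""
        nodes = ("A", "B", "C")
        A = rng.standard_normal((3, 6))
        R = np.corrcoef(A)
        corr = CorrelationMatrix(R, nodes, 250)
        dags = enumerate_dags(nodes)

        def fingerprint(dag):
            stmts = []
            for x, y in itertools.combinations(nodes, 2):
                others = [v for v in nodes if v not in (x, y)]
                for k in range(len(others) + 1):
                    for zs in itertools.combinations(others, k):
                        stmts.append(d_separated(dag, x, y, set(zs)))
            return tuple(stmts)

        groups: dict[tuple, list[float]] = {}
        for dag in dags:
            groups.setdefault(fingerprint(dag), []).append(
                bic_score(corr, dag, 250))
        for scores in groups.values():
            assert np.ptp(scores) < 1e-9


class TestScoreSubset:
    def test_posteriors_normalise(self):
        s = score_subset(corr2(0.4), ("X", "Y"), 100)
        assert s.posteriors.sum() == pytest.approx(1.0)
        assert len(s.dags) == 3

    def test_independent_pair_favours_the_empty_dag(self):
        for m in (10, 100, 1000):
            s = score_subset(corr2(0.0, m), ("X", "Y"), m)
            empty = [i for i, d in enumerate(s.dags) if not d.edges][0]
            assert np.argmax(s.posteriors) == empty

    def test_strong_dependence_concentrates_on_connected_dags(self):
        s = score_subset(corr2(0.9, 500), ("X", "Y"), 500)
        connected = np.array([bool(d.edges) for d in s.dags])
        assert s.posteriors[connected].sum() > 0.99

    def test_window_size_guard(self):
        nodes = tuple("ABCDEF")
        corr = CorrelationMatrix(np.eye(6), nodes, 50)
        with pytest.raises(ValueError, match="1..5"):
            score_subset(corr, nodes, 50)


class TestStatementReliability:
    def test_universally_entailed_statement_has_reliability_one(self):
        s = score_subset(corr2(0.5), ("X", "Y"), 100)
        # "X and Y dependent or independent" is a partition: dependence +
        # independence reliabilities must sum to one
        ind = statement_reliability(s, CausalStatement("independence", "X", "Y"))
        dep = statement_reliability(s, CausalStatement("dependence", "X", "Y"))
        assert ind + dep == pytest.approx(1.0)

    def test_two_variable_independence_equals_empty_dag_posterior(self):
        s = score_subset(corr2(0.3), ("X", "Y"), 200)
        empty = [i for i, d in enumerate(s.dags) if not d.edges][0]
        ind = statement_reliability(s, CausalStatement("independence", "X", "Y"))
        assert ind == pytest.approx(s.posteriors[empty])

    def test_cause_statements_partition_with_no_edge_case(self):
        s = score_subset(corr2(0.8, 500), ("X", "Y"), 500)
        pxy = statement_reliability(s, CausalStatement("cause", "X", "Y"))
        pyx = statement_reliability(s, CausalStatement("cause", "Y", "X"))
        ind = statement_reliability(s, CausalStatement("independence", "X", "Y"))
        assert pxy + pyx + ind == pytest.approx(1.0)
        assert pxy == pytest.approx(pyx)  # symmetric evidence

    def test_unknown_kind_and_foreign_variable_rejected(self):
        s = score_subset(corr2(0.5), ("X", "Y"), 100)
        with pytest.raises(ValueError, match="kind"):
            CausalStatement("confounded", "X", "Y")
        with pytest.raises(ValueError, match="not in window"):
            statement_reliability(s, CausalStatement("cause", "X", "Q"))


class TestAdjacencySearch:
    def test_independent_pair_edge_removed(self):
        res = adjacency_search(corr2(0.0, 1000), 1000, threshold=0.6)
        assert res.skeleton == set()
        assert frozenset(("X", "Y")) in res.sepsets

    def test_dependent_pair_edge_retained(self):
        res = adjacency_search(corr2(0.9, 500), 500, threshold=0.01 + 0.5)
        assert res.skeleton == {frozenset(("X", "Y"))}

    def test_chain_oracle_removes_only_the_shielded_pair(self):
        nodes, edges = BENCHMARK_DAGS["chain3"]
        corr = linear_sem_correlation(DAG(tuple(nodes), edges), coef=0.8)
        res = adjacency_search(corr, 1000)
        assert res.skeleton == {frozenset("AB"), frozenset("BC")}
        assert res.sepsets[frozenset("AC")] == ("B",)

    @pytest.mark.parametrize("name", sorted(BENCHMARK_DAGS))
    def test_oracle_skeleton_recovery_on_benchmark_dags(self, name):
        nodes, edges = BENCHMARK_DAGS[name]
        dag = DAG(tuple(nodes), edges)
        corr = linear_sem_correlation(dag)
        res = adjacency_search(corr, 10_000)
        assert res.skeleton == dag.skeleton()


class TestOrientation:
    def test_no_reliable_statement_leaves_all_circles(self):
        skeleton = {frozenset("AB"), frozenset("BC")}
        table = ReliabilityTable()
        for x, y in (("A", "B"), ("B", "A"), ("B", "C"), ("C", "B")):
            table.add(CausalStatement("cause", x, y), 0.5, (x, y))
        pag = orient_edges(skeleton, table)
        for x, y in (("A", "B"), ("B", "C")):
            assert pag.mark(x, y) is Mark.CIRCLE
            assert pag.mark(y, x) is Mark.CIRCLE

    def test_collider_oracle_is_fully_oriented(self):
        nodes, edges = BENCHMARK_DAGS["collider3"]
        dag = DAG(tuple(nodes), edges)
        corr = linear_sem_correlation(dag, coef=0.7)
        res = adjacency_search(corr, 5000)
        table = causal_reliabilities(corr, 5000, res.skeleton, res.windows)
        pag = orient_edges(res.skeleton, table)
        assert pag.mark("A", "B") is Mark.ARROW
        assert pag.mark("C", "B") is Mark.ARROW

    def test_conflicting_statements_resolved_by_reliability(self):
        skeleton = {frozenset("AB")}
        table = ReliabilityTable()
        table.add(CausalStatement("cause", "A", "B"), 0.9, ("A", "B"))
        table.add(CausalStatement("cause", "B", "A"), 0.7, ("A", "B"))
        pag = orient_edges(skeleton, table)
        # the stronger statement wins: A -> B; the weaker one is skipped
        assert pag.mark("A", "B") is Mark.ARROW
        assert pag.mark("B", "A") is Mark.TAIL

    def test_background_forbids_causes_of_a_root_variable(self):
        # G -> X -> Y with G protected by "nothing causes G"
        dag = DAG(("G", "X", "Y"), [("G", "X"), ("X", "Y")])
        corr = linear_sem_correlation(dag, coef=0.7)
        background = BackgroundKnowledge([("*", "G")])
        res = adjacency_search(corr, 5000, background=background)
        table = causal_reliabilities(corr, 5000, res.skeleton, res.windows,
                                     background)
        pag = orient_edges(res.skeleton, table, background)
        assert pag.has_edge("G", "X")
        # no mark may claim X causes G: the G end is never an arrowhead-free
        # tail claim from X's side, and the X end carries the arrowhead
        assert pag.mark("G", "X") is Mark.ARROW
        assert pag.mark("X", "G") is Mark.TAIL


class TestBackgroundKnowledge:
    def test_parsing_and_wildcards(self):
        bk = BackgroundKnowledge.from_lines(
            ["# comment", "forbid A -> B", "forbid * -> G", ""])
        assert bk.forbids("A", "B")
        assert bk.forbids("Q", "G")
        assert not bk.forbids("B", "A")

    def test_malformed_line_and_self_loop_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            BackgroundKnowledge.from_lines(["A causes B"])
        with pytest.raises(ValueError, match="inconsistent"):
            BackgroundKnowledge([("A", "A")])

    def test_unknown_variable_rejected_at_validation(self):
        bk = BackgroundKnowledge([("A", "Q")])
        with pytest.raises(ValueError, match="unknown"):
            bk.validate(("A", "B"))

    def test_constraint_restricts_the_hypothesis_space(self):
        bk = BackgroundKnowledge([("X", "Y")])
        s = score_subset(corr2(0.9, 500), ("X", "Y"), 500, background=bk)
        assert statement_reliability(
            s, CausalStatement("cause", "X", "Y")) == 0.0
        assert statement_reliability(
            s, CausalStatement("cause", "Y", "X")) > 0.99


class TestRunBCCD:
    def test_independent_columns_yield_empty_graph(self, rng):
        frame = pd.DataFrame(rng.standard_normal((500, 4)),
                             columns=list("WXYZ"))
        data = MixedDataset(frame, {c: "continuous" for c in frame})
        out = run_bccd(data, estimator="em")
        assert out.pag.edges() == set()

    def test_reliabilities_are_probabilities(self, rng):
        frame = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("XYZ"))
        frame["Y"] += frame["X"]
        data = MixedDataset(frame, {c: "continuous" for c in frame})
        out = run_bccd(data)
        assert all(0 <= p <= 1 for _, p, _ in out.reliabilities.entries)
        assert all(0 <= p <= 1 for p in out.edge_reliability.values())

    def test_skeleton_recall_on_benchmark_samples(self):
        """Medium-correlation benchmark, n = 1000, no missing values: the
        skeleton recall reaches 0.8 in at least 80% of 50 seeded runs."""
        from copulacd import (distort, ground_truth_pag,
                              skeleton_precision_recall, waste_incinerator,
                              sample_network)
        from copulacd.graphs import PAG

        net = waste_incinerator("medium")
        truth = ground_truth_pag(net.dag)
        hits = 0
        for seed in range(50):
            data = distort(sample_network(net, 1000, seed=seed))
            out = run_bccd(data, estimator="em")
            est = PAG(net.nodes)
            for e in out.skeleton:
                est.add_edge(*sorted(e))
            _, recall = skeleton_precision_recall(est, truth)
            hits += recall >= 0.8
        assert hits >= 40

    def test_recovers_chain_skeleton_from_sampled_data(self, rng):
        n = 1000
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        c = 0.8 * b + 0.6 * rng.standard_normal(n)
        frame = pd.DataFrame({"A": a, "B": b, "C": c})
        data = MixedDataset(frame, {k: "continuous" for k in frame})
        out = run_bccd(data)
        assert out.skeleton == {frozenset("AB"), frozenset("BC")}
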