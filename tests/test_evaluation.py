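import itertools

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from grninfer.data_io import GoldStandard, TFList
from grninfer.evaluation import (
    DEFAULT_RELEVANCES,
    CausalCategory,
    FalsePositiveClassifier,
    auroc_aupr,
    classify_false_positive,
    evaluate,
    matrix_symmetry,
    ndcg_score,
    overall_from_pvalues,
    overall_score,
)

C = CausalCategory


def score_matrix(m, pair_scores):
    M = np.zeros((m, m))
    for (i, j), s in pair_scores.items():
        M[i, j] = s
    return M


# ---------------------------------------------------------------------------
# independent oracles


def mann_whitney_auroc(scores, labels):
    """Brute-force pair counting."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def simple_path_exists(edges, u, v, nodes):
    """Exhaustive simple-path enumeration (directed)."""
    edge_set = set(edges)
    others = [x for x in nodes if x not in (u, v)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            seq = (u, *mid, v)
            if all((a, b) in edge_set for a, b in zip(seq, seq[1:])):
                return True
    return False


def oracle_classify(edges, i, j, nodes):
    if (i, j) in edges:
        return C.TRUE_POSITIVE
    if simple_path_exists(edges, i, j, nodes):
        return C.CHAIN
    if simple_path_exists(edges, j, i, nodes):
        return C.REVERSED_CHAIN
    for c in nodes:
        if c in (i, j):
            continue
        if simple_path_exists(edges, c, i, nodes) and simple_path_exists(edges, c, j, nodes):
            return C.FORK
    for c in nodes:
        if c in (i, j):
            continue
        if simple_path_exists(edges, i, c, nodes) and simple_path_exists(edges, j, c, nodes):
            return C.COLLIDER
    undirected = edges | {(b, a) for a, b in edges}
    if simple_path_exists(undirected, i, j, nodes):
        return C.UNDIRECTED
    return C.SPURIOUS


# ---------------------------------------------------------------------------


class TestAurocAupr:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.m = 12
        pairs = [(i, j) for i in range(self.m) for j in range(self.m) if i != j]
        self.edges = {pairs[k] for k in rng.choice(len(pairs), 20, replace=False)}
        self.gold = GoldStandard(self.edges, self.m)

    def test_perfect_ranking(self):
        M = score_matrix(self.m, {e: 1.0 for e in self.edges})
        auroc, aupr = auroc_aupr(M, self.gold)
        assert auroc == pytest.approx(1.0)
        assert aupr == pytest.approx(1.0)

    def test_reversed_ranking(self):
        M = score_matrix(self.m, {})
        for i in range(self.m):
            for j in range(self.m):
                if i != j and (i, j) not in self.edges:
                    M[i, j] = 1.0 + i * self.m + j
        auroc, _ = auroc_aupr(M, self.gold)
        assert auroc == pytest.approx(0.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        m = 46  # ~2000 candidate pairs
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        edges = {pairs[k] for k in rng.choice(len(pairs), 100, replace=False)}
        gold = GoldStandard(edges, m)
        M = rng.random((m, m))
        np.fill_diagonal(M, 0.0)
        auroc, _ = auroc_aupr(M, gold)
        assert 0.45 <= auroc <= 0.55

    @pytest.mark.parametrize("seed", range(5))
    def test_auroc_matches_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = 10  # <= 200 candidate pairs
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        edges = {pairs[k] for k in rng.choice(len(pairs), 12, replace=False)}
        gold = GoldStandard(edges, m)
        M = rng.integers(0, 5, size=(m, m)).astype(float)  # plenty of ties
        np.fill_diagonal(M, 0.0)
        auroc, aupr = auroc_aupr(M, gold)
        ii, jj = np.nonzero(~np.eye(m, dtype=bool))
        scores = M[ii, jj]
        labels = np.array([(i, j) in edges for i, j in zip(ii, jj)])
        assert auroc == pytest.approx(mann_whitney_auroc(scores, labels), abs=1e-12)
        # dual-route check against sklearn
        assert auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert aupr == pytest.approx(average_precision_score(labels, scores), abs=1e-12)

    def test_tf_universe_restriction(self):
        tfs = TFList(frozenset({0, 1}), self.m)
        sub_edges = {e for e in self.edges if e[0] in (0, 1)}
        if not sub_edges:
            pytest.skip("no edges from the chosen TFs in this draw")
        M = score_matrix(self.m, {e: 1.0 for e in self.edges})
        auroc, _ = auroc_aupr(M, self.gold, tfs)
        assert auroc == pytest.approx(1.0)

    def test_no_positives_is_error(self):
        gold = GoldStandard({(5, 6)}, self.m)
        tfs = TFList(frozenset({0}), self.m)
        with pytest.raises(ValueError):
            auroc_aupr(np.zeros((self.m, self.m)), gold, tfs)

    def test_restrict_to_known(self):
        gold = GoldStandard({(0, 1)}, 3, declared_negatives={(0, 2)})
        M = score_matrix(3, {(0, 1): 0.5, (0, 2): 1.0, (1, 2): 2.0})
        # unrestricted: (1,2) outranks the positive
        auroc_all, _ = auroc_aupr(M, gold)
        auroc_known, _ = auroc_aupr(M, gold, restrict_to_known=True)
        assert auroc_known == pytest.approx(0.0)  # only (0,2) competes, and wins
        assert auroc_all < 1.0


class TestOverallScore:
    def test_closed_form_identity(self):
        assert overall_from_pvalues(1.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert overall_from_pvalues(0.01, 0.01) == pytest.approx(2.0, abs=1e-12)

    def test_pvalue_out_of_range(self):
        with pytest.raises(ValueError):
            overall_from_pvalues(0.0, 0.5)

    def test_perfect_ranking_hits_pvalue_floor(self):
        rng = np.random.default_rng(0)
        m = 46
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        edges = {pairs[k] for k in rng.choice(len(pairs), 100, replace=False)}
        gold = GoldStandard(edges, m)
        M = score_matrix(m, {e: 1.0 for e in edges})
        report = overall_score(M, gold, null_reps=999, seed=0)
        assert report.p_auroc == pytest.approx(1 / 1000)
        assert report.p_aupr == pytest.approx(1 / 1000)
        assert report.overall_score == pytest.approx(3.0, abs=1e-12)

    def test_random_scores_insignificant(self):
        rng = np.random.default_rng(3)
        m = 20
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        edges = {pairs[k] for k in rng.choice(len(pairs), 30, replace=False)}
        gold = GoldStandard(edges, m)
        M = rng.random((m, m))
        np.fill_diagonal(M, 0.0)
        report = overall_score(M, gold, null_reps=200, seed=1)
        assert report.p_auroc > 0.05 or report.p_aupr > 0.05

    def test_small_reps_warns(self):
        gold = GoldStandard({(0, 1)}, 3)
        M = score_matrix(3, {(0, 1): 1.0})
        with pytest.warns(UserWarning, match="coarse"):
            overall_score(M, gold, null_reps=10, seed=0)


class TestClassifyFalsePositive:
    def test_chain(self):
        gold = GoldStandard({(0, 1), (1, 2)}, 3)
        assert classify_false_positive((0, 2), gold) == C.CHAIN

    def test_fork(self):
        gold = GoldStandard({(0, 1), (0, 2)}, 3)
        assert classify_false_positive((1, 2), gold) == C.FORK

    def test_collider(self):
        gold = GoldStandard({(0, 2), (1, 2)}, 3)
        assert classify_false_positive((0, 1), gold) == C.COLLIDER

    def test_reversed_chain(self):
        gold = GoldStandard({(0, 1), (1, 2)}, 3)
        assert classify_false_positive((2, 0), gold) == C.REVERSED_CHAIN

    def test_spurious(self):
        gold = GoldStandard({(0, 1)}, 4)
        assert classify_false_positive((2, 3), gold) == C.SPURIOUS

    def test_undirected(self):
        # 0->1<-2->3: (0,3) shares the skeleton but no directed structure
        gold = GoldStandard({(0, 1), (2, 1), (2, 3)}, 4)
        assert classify_false_positive((0, 3), gold) == C.UNDIRECTED

    def test_true_positive_and_self_loop(self):
        gold = GoldStandard({(0, 1)}, 2)
        assert classify_false_positive((0, 1), gold) == C.TRUE_POSITIVE
        with pytest.raises(ValueError):
            classify_false_positive((1, 1), gold)

    def test_cycle_handled(self):
        gold = GoldStandard({(0, 1), (1, 0), (1, 2)}, 4)
        clf = FalsePositiveClassifier(gold)
        assert clf.classify(0, 2) == C.CHAIN
        assert clf.classify(2, 0) == C.REVERSED_CHAIN

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        nodes = range(5)
        candidates = [(i, j) for i in nodes for j in nodes if i < j]
        mask = rng.random(len(candidates)) < 0.4
        edges = {c for c, keep in zip(candidates, mask) if keep}
        gold = GoldStandard(edges, 5)
        clf = FalsePositiveClassifier(gold)
        for i in nodes:
            for j in nodes:
                if i != j:
                    assert clf.classify(i, j) == oracle_classify(edges, i, j, set(nodes)), (
                        edges, i, j
                    )


class TestNDCG:
    def test_perfect_topk_is_one(self):
        gold = GoldStandard({(0, 1), (1, 2), (0, 3)}, 4)
        assert ndcg_score([(0, 1), (1, 2)], gold, k=2) == pytest.approx(1.0)

    def test_degrading_one_slot_strictly_decreases(self):
        gold = GoldStandard({(0, 1), (1, 2), (0, 3)}, 4)
        perfect = ndcg_score([(0, 1), (1, 2)], gold, k=2)
        degraded = ndcg_score([(0, 1), (0, 2)], gold, k=2)  # TP -> chain
        worse = ndcg_score([(0, 1), (2, 1)], gold, k=2)  # TP -> collider? check below
        assert degraded < perfect
        assert ndcg_score([(0, 1), (3, 2)], gold, k=2) < degraded  # chain -> worse category
        assert worse < perfect

    def test_hand_example_custom_relevances(self):
        gold = GoldStandard({(0, 1), (1, 2)}, 3)
        relevances = {
            C.TRUE_POSITIVE: 4.0,
            C.CHAIN: 3.0,
            C.FORK: 2.0,
            C.REVERSED_CHAIN: 2.0,
            C.COLLIDER: 1.0,
            C.UNDIRECTED: 1.0,
            C.SPURIOUS: 0.0,
        }
        got = ndcg_score([(0, 1), (0, 2)], gold, k=2, relevances=relevances)
        # hand-evaluated DCG formula: slots discounted by 1/log2(r+1)
        dcg = 4.0 / np.log2(2) + 3.0 / np.log2(3)
        ideal = 4.0 / np.log2(2) + 4.0 / np.log2(3)
        assert got == pytest.approx(dcg / ideal, abs=1e-12)
        assert got == pytest.approx(0.9032868, abs=1e-6)

    def test_monotone_in_category_at_fixed_rank(self):
        # same graph offers pairs of every category; upgrading rank-2 must
        # never decrease the score
        gold = GoldStandard({(0, 1), (1, 2), (0, 3), (4, 3)}, 6)
        ladder = [(5, 4), (0, 4), (3, 2), (2, 0), (0, 2), (1, 2)]
        clf = FalsePositiveClassifier(gold)
        relevance = [DEFAULT_RELEVANCES[clf.classify(*p)] for p in ladder]
        assert relevance == sorted(relevance)  # ladder is ordered worst->best
        values = [ndcg_score([(0, 1), p], gold, k=2) for p in ladder]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_relevance_ordering_enforced(self):
        gold = GoldStandard({(0, 1)}, 2)
        bad = dict(DEFAULT_RELEVANCES)
        bad[C.SPURIOUS] = 10.0
        with pytest.raises(ValueError):
            ndcg_score([(0, 1)], gold, k=1, relevances=bad)

    def test_empty_ranking_warns_zero(self):
        gold = GoldStandard({(0, 1)}, 2)
        with pytest.warns(UserWarning, match="empty"):
            assert ndcg_score(np.zeros((2, 2)), gold, k=3) == 0.0

    def test_matrix_input_matches_pair_input(self):
        gold = GoldStandard({(0, 1), (1, 2)}, 3)
        M = score_matrix(3, {(0, 1): 3.0, (0, 2): 2.0, (2, 1): 1.0})
        assert ndcg_score(M, gold, k=3) == pytest.approx(
            ndcg_score([(0, 1), (0, 2), (2, 1)], gold, k=3)
        )


class TestMatrixSymmetry:
    def test_symmetric_is_one(self):
        rng = np.random.default_rng(0)
        S = rng.random((5, 5))
        S = S + S.T
        assert matrix_symmetry(S) == pytest.approx(1.0)

    def test_disjoint_triangles_zero(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[2, 1] = M[0, 2] = 1.0  # wherever M_ij > 0, M_ji == 0
        assert matrix_symmetry(M) == pytest.approx(0.0)

    def test_one_sided_support_zero(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[0, 2] = M[1, 2] = 1.0  # upper triangle only
        assert matrix_symmetry(M) == pytest.approx(0.0)

    def test_continuity_in_antisymmetric_perturbation(self):
        rng = np.random.default_rng(1)
        S = rng.random((6, 6))
        S = S + S.T
        A = rng.standard_normal((6, 6))
        A = A - A.T
        values = [matrix_symmetry(S + eps * A) for eps in (0.5, 0.1, 0.01)]
        assert values == sorted(values)
        assert values[-1] > 0.999

    def test_zero_matrix_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(matrix_symmetry(np.zeros((4, 4))))


class TestEvaluate:
    def test_full_report(self):
        rng = np.random.default_rng(0)
        m = 15
        pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
        edges = {pairs[k] for k in rng.choice(len(pairs), 25, replace=False)}
        gold = GoldStandard(edges, m)
        M = score_matrix(m, {e: 1.0 + rng.random() for e in edges})
        report = evaluate(M, gold, k=10, null_reps=200, seed=0)
        assert report.auroc == pytest.approx(1.0)
        assert report.overall_score == pytest.approx(
            overall_from_pvalues(report.p_auroc, report.p_aupr), abs=1e-12
        )
        assert report.ndcg == pytest.approx(1.0)
        assert report.fp_category_counts == {}
        assert 0.0 <= report.symmetry <= 1.0
        payload = report.to_dict()
        assert set(payload["relevances"]) == {c.value for c in CausalCategory}
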