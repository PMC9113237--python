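"""Scoring of inferred rankings against a goldstandard network.

Provides AUROC/AUPR over the candidate-edge universe, a Monte-Carlo
overall score ``-0.5 * log10(p_auroc * p_aupr)`` whose p-values come from
score permutations over the universe, a causal-structure taxonomy of false
positives (chain / reversed chain / fork / collider / undirected /
spurious), a relevance-weighted NDCG over that taxonomy, and a symmetry
diagnostic for score matrices.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from collections import Counter
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .data_io import EdgeRanking, GoldStandard, TFList, ranking_to_matrix

__all__ = [
    "CausalCategory",
    "DEFAULT_RELEVANCES",
    "EvaluationReport",
    "FalsePositiveClassifier",
    "auroc_aupr",
    "overall_from_pvalues",
    "overall_score",
    "classify_false_positive",
    "ndcg_score",
    "matrix_symmetry",
    "evaluate",
]


class CausalCategory(enum.Enum):
    """Causal structure explaining a predicted pair, by decreasing relevance."""

    TRUE_POSITIVE = "true_positive"
    CHAIN = "chain"
    FORK = "fork"
    REVERSED_CHAIN = "reversed_chain"
    COLLIDER = "collider"
    UNDIRECTED = "undirected"
    SPURIOUS = "spurious"


#: default relevance grades; the contract is the ordering
#: TP > chain > fork = reversed chain > collider = undirected > spurious
DEFAULT_RELEVANCES: Mapping[CausalCategory, float] = {
    CausalCategory.TRUE_POSITIVE: 5.0,
    CausalCategory.CHAIN: 4.0,
    CausalCategory.FORK: 3.0,
    CausalCategory.REVERSED_CHAIN: 3.0,
    CausalCategory.COLLIDER: 2.0,
    CausalCategory.UNDIRECTED: 2.0,
    CausalCategory.SPURIOUS: 0.0,
}


def _check_relevances(relevances: Mapping[CausalCategory, float]) -> None:
    r = {c: float(relevances[c]) for c in CausalCategory}
    C = CausalCategory
    ok = (
        r[C.TRUE_POSITIVE] > r[C.CHAIN] > r[C.FORK] == r[C.REVERSED_CHAIN]
        > r[C.COLLIDER] == r[C.UNDIRECTED] > r[C.SPURIOUS] >= 0.0
    )
    if not ok:
        raise ValueError("relevance grades violate the category ordering")


@dataclasses.dataclass
class EvaluationReport:
    """All figures of merit for one inferred network."""

    auroc: float
    aupr: float
    p_auroc: float | None = None
    p_aupr: float | None = None
    overall_score: float | None = None
    ndcg: float | None = None
    fp_category_counts: dict = dataclasses.field(default_factory=dict)
    symmetry: float | None = None
    relevances: dict = dataclasses.field(default_factory=dict)
    k: int | None = None
    null_reps: int | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["fp_category_counts"] = {
            (c.value if isinstance(c, CausalCategory) else c): n
            for c, n in self.fp_category_counts.items()
        }
        out["relevances"] = {
            (c.value if isinstance(c, CausalCategory) else c): v
            for c, v in self.relevances.items()
        }
        return out


# ---------------------------------------------------------------------------
# candidate universe and threshold metrics


def _candidate_universe(
    gold: GoldStandard, tfs: TFList | None, restrict_to_known: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (ii, jj) of candidate pairs and their binary labels."""
    m = gold.n_genes
    if tfs is None:
        tfs = TFList.all_genes(m)
    tf_mask = tfs.mask()
    ii, jj = np.nonzero(tf_mask[:, np.newaxis] & ~np.eye(m, dtype=bool))
    if restrict_to_known:
        known = gold.edges | gold.declared_negatives
        keep = np.fromiter(
            ((int(i), int(j)) in known for i, j in zip(ii, jj)), bool, len(ii)
        )
        ii, jj = ii[keep], jj[keep]
    labels = np.fromiter(
        ((int(i), int(j)) in gold.edges for i, j in zip(ii, jj)), bool, len(ii)
    )
    return ii, jj, labels


def _scores_matrix(scores, gold: GoldStandard) -> np.ndarray:
    if isinstance(scores, EdgeRanking):
        raise TypeError("resolve an EdgeRanking to a matrix with gene names first")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (gold.n_genes, gold.n_genes):
        raise ValueError("score matrix shape does not match the goldstandard")
    return scores


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with midranks for ties (Mann-Whitney statistic)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise precision-recall integration, tied scores grouped."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    boundaries = np.flatnonzero(np.diff(s))
    boundaries = np.append(boundaries, s.size - 1)
    tp = np.cumsum(y)[boundaries]
    n_seen = boundaries + 1.0
    precision = tp / n_seen
    recall = tp / labels.sum()
    return float(np.sum(np.diff(np.concatenate(([0.0], recall))) * precision))


def auroc_aupr(
    scores,
    gold: GoldStandard,
    tfs: TFList | None = None,
    *,
    restrict_to_known: bool = False,
) -> tuple[float, float]:
    """AUROC and AUPR of a score matrix over the candidate-pair universe.

    The universe is every ordered (regulator in TF list, target) pair minus
    self-loops; unknown pairs count as negatives unless
    ``restrict_to_known`` limits the universe to edges plus declared
    negatives.  Unranked (zero-score) pairs share the worst rank, ties are
    midranked.
    """
    S = _scores_matrix(scores, gold)
    ii, jj, labels = _candidate_universe(gold, tfs, restrict_to_known)
    if not labels.any():
        raise ValueError("no goldstandard edges in the candidate universe")
    if labels.all():
        raise ValueError("no negative pairs in the candidate universe")
    values = S[ii, jj]
    return _auroc(values, labels), _aupr(values, labels)


# ---------------------------------------------------------------------------
# Monte-Carlo overall score


def overall_from_pvalues(p_auroc: float, p_aupr: float) -> float:
    """Closed-form overall score ``-0.5 * log10(p_auroc * p_aupr)``."""
    if not (0 < p_auroc <= 1 and 0 < p_aupr <= 1):
        raise ValueError("p-values must lie in (0, 1]")
    return -0.5 * np.log10(p_auroc * p_aupr)


def overall_score(
    scores,
    gold: GoldStandard,
    tfs: TFList | None = None,
    *,
    null_reps: int = 1000,
    seed: int = 0,
    restrict_to_known: bool = False,
) -> EvaluationReport:
    """Overall score from Monte-Carlo p-values of AUROC and AUPR.

    The null model permutes the candidate-pair scores uniformly; p-values
    use the add-one estimator ``(1 + #{null >= observed}) / (R + 1)`` and
    are therefore floored at ``1 / (R + 1)``.
    """
    if null_reps < 1:
        raise ValueError("null_reps must be >= 1")
    if null_reps < 100:
        warnings.warn(
            f"null_reps={null_reps} gives a coarse p-value floor of "
            f"{1 / (null_reps + 1):.3g}",
            stacklevel=2,
        )
    S = _scores_matrix(scores, gold)
    ii, jj, labels = _candidate_universe(gold, tfs, restrict_to_known)
    values = S[ii, jj]
    auroc = _auroc(values, labels)
    aupr = _aupr(values, labels)

    # permuting scores over the universe is equivalent to permuting labels,
    # which lets the sorted score vector and its tie groups be reused
    rng = np.random.default_rng(seed)
    order = np.argsort(-values, kind="stable")
    s_sorted = values[order]
    boundaries = np.flatnonzero(np.diff(s_sorted))
    boundaries = np.append(boundaries, s_sorted.size - 1)
    n_seen = boundaries + 1.0
    ranks = stats.rankdata(values)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    n_ge_auroc = 0
    n_ge_aupr = 0
    for _ in range(null_reps):
        perm_labels = rng.permutation(labels)
        null_auroc = (ranks[perm_labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        y = perm_labels[order].astype(float)
        tp = np.cumsum(y)[boundaries]
        precision = tp / n_seen
        recall = tp / n_pos
        null_aupr = np.sum(np.diff(np.concatenate(([0.0], recall))) * precision)
        n_ge_auroc += null_auroc >= auroc
        n_ge_aupr += null_aupr >= aupr
    p_auroc = (1 + n_ge_auroc) / (null_reps + 1)
    p_aupr = (1 + n_ge_aupr) / (null_reps + 1)
    return EvaluationReport(
        auroc=auroc,
        aupr=aupr,
        p_auroc=p_auroc,
        p_aupr=p_aupr,
        overall_score=overall_from_pvalues(p_auroc, p_aupr),
        null_reps=null_reps,
    )


# ---------------------------------------------------------------------------
# causal-structure taxonomy


class FalsePositiveClassifier:
    """Classify predicted pairs by the causal structure around them.

    Reachability is computed once on the goldstandard graph (cycles are
    handled through strongly-connected-component condensation), after which
    each pair is classified by the first matching rule: gold edge (true
    positive), directed path regulator->target (chain), directed path
    target->regulator (reversed chain), common ancestor (fork), common
    descendant (collider), connected in the undirected skeleton
    (undirected), else spurious.
    """

    def __init__(self, gold: GoldStandard):
        self.gold = gold
        m = gold.n_genes
        graph = nx.DiGraph()
        graph.add_nodes_from(range(m))
        graph.add_edges_from(gold.edges)

        reach = np.zeros((m, m), dtype=bool)
        condensation = nx.condensation(graph)
        scc_members = {c: data["members"] for c, data in condensation.nodes(data=True)}
        scc_reach: dict[int, set] = {}
        for c in reversed(list(nx.topological_sort(condensation))):
            down = set(condensation.successors(c))
            for child in list(down):
                down |= scc_reach[child]
            scc_reach[c] = down
            members = list(scc_members[c])
            targets = set(members) if len(members) > 1 else set()
            for d in down:
                targets |= scc_members[d]
            if targets:
                reach[np.ix_(members, sorted(targets))] = True
        self.reach = reach

        component = np.zeros(m, dtype=int)
        for k, comp in enumerate(nx.connected_components(graph.to_undirected())):
            component[list(comp)] = k
        self._component = component
        self._edge = np.zeros((m, m), dtype=bool)
        for i, j in gold.edges:
            self._edge[i, j] = True

    def classify(self, regulator: int, target: int) -> CausalCategory:
        i, j = int(regulator), int(target)
        if i == j:
            raise ValueError("cannot classify a self-loop")
        if self._edge[i, j]:
            return CausalCategory.TRUE_POSITIVE
        if self.reach[i, j]:
            return CausalCategory.CHAIN
        if self.reach[j, i]:
            return CausalCategory.REVERSED_CHAIN
        if bool(np.any(self.reach[:, i] & self.reach[:, j])):
            return CausalCategory.FORK
        if bool(np.any(self.reach[i, :] & self.reach[j, :])):
            return CausalCategory.COLLIDER
        if self._component[i] == self._component[j]:
            return CausalCategory.UNDIRECTED
        return CausalCategory.SPURIOUS

    def best_achievable_fp_relevance(
        self, relevances: Mapping[CausalCategory, float]
    ) -> float:
        """Highest relevance reachable by any non-edge candidate pair."""
        m = self.gold.n_genes
        offdiag = ~np.eye(m, dtype=bool)
        non_edge = offdiag & ~self._edge
        checks = [
            (CausalCategory.CHAIN, self.reach),
            (CausalCategory.REVERSED_CHAIN, self.reach.T),
            (CausalCategory.FORK, self.reach.T @ self.reach),
            (CausalCategory.COLLIDER, self.reach @ self.reach.T),
            (
                CausalCategory.UNDIRECTED,
                self._component[:, np.newaxis] == self._component[np.newaxis, :],
            ),
        ]
        best = relevances[CausalCategory.SPURIOUS]
        for category, indicator in checks:
            if np.any(np.asarray(indicator, dtype=bool) & non_edge):
                best = relevances[category]
                break
        return float(best)


def classify_false_positive(pair: tuple, gold: GoldStandard) -> CausalCategory:
    """One-off classification of a single (regulator, target) pair."""
    return FalsePositiveClassifier(gold).classify(*pair)


# ---------------------------------------------------------------------------
# relevance-weighted NDCG


def _ordered_pairs(predictions, gene_names: Sequence[str] | None) -> list:
    if isinstance(predictions, EdgeRanking):
        if gene_names is None:
            raise ValueError("gene_names is required to resolve an EdgeRanking")
        return predictions.pairs(gene_names)
    predictions = np.asarray(predictions)
    if predictions.ndim == 2 and predictions.shape[0] == predictions.shape[1] and (
        predictions.shape[0] > 2 or predictions.dtype != int
    ):
        ii, jj = np.nonzero(predictions)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        order = np.lexsort((jj, ii, -predictions[ii, jj]))
        return [(int(i), int(j)) for i, j in zip(ii[order], jj[order])]
    return [(int(i), int(j)) for i, j in predictions]


def ndcg_score(
    predictions,
    gold: GoldStandard,
    k: int,
    relevances: Mapping[CausalCategory, float] | None = None,
    gene_names: Sequence[str] | None = None,
) -> float:
    """Relevance-weighted normalized discounted cumulative gain at ``k``.

    ``DCG = sum_r relevance(category of prediction r) / log2(r + 1)`` over
    the top-``k`` predictions, normalized by the ideal DCG: true positives
    in the top slots (capped at the number of gold edges) and the best
    achievable false-positive category in the remainder.

    ``predictions`` may be an :class:`EdgeRanking` (with ``gene_names``), an
    ordered sequence of (regulator, target) index pairs, or a score matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    relevances = dict(DEFAULT_RELEVANCES if relevances is None else relevances)
    _check_relevances(relevances)
    pairs = _ordered_pairs(predictions, gene_names)[:k]
    if not pairs:
        warnings.warn("empty ranking: NDCG reported as 0", stacklevel=2)
        return 0.0
    classifier = FalsePositiveClassifier(gold)
    discounts = 1.0 / np.log2(np.arange(1, k + 1) + 1)
    gains = np.zeros(k)
    for r, (i, j) in enumerate(pairs):
        gains[r] = relevances[classifier.classify(i, j)]
    dcg = float(np.sum(gains * discounts))

    n_tp_slots = min(k, gold.n_edges)
    ideal_gains = np.full(k, classifier.best_achievable_fp_relevance(relevances))
    ideal_gains[:n_tp_slots] = relevances[CausalCategory.TRUE_POSITIVE]
    ideal = float(np.sum(ideal_gains * discounts))
    if ideal <= 0:
        return 0.0
    return dcg / ideal


# ---------------------------------------------------------------------------
# symmetry diagnostic


def matrix_symmetry(M: np.ndarray) -> float:
    """Cosine similarity of the off-diagonal upper and lower triangles.

    1 means perfectly symmetric scores; 0 means the two triangles carry
    disjoint support (including one triangle being empty).  Undefined
    (NaN) for an all-zero matrix.
    """
    M = np.asarray(M, dtype=float)
    iu = np.triu_indices(M.shape[0], k=1)
    upper = M[iu]
    lower = M.T[iu]
    nu, nl = np.linalg.norm(upper), np.linalg.norm(lower)
    if nu == 0 and nl == 0:
        warnings.warn("zero matrix: symmetry undefined", stacklevel=2)
        return float("nan")
    if nu == 0 or nl == 0:
        return 0.0
    return float(np.clip(np.dot(upper, lower) / (nu * nl), 0.0, 1.0))


# ---------------------------------------------------------------------------
# orchestrator


def evaluate(
    scores,
    gold: GoldStandard,
    tfs: TFList | None = None,
    *,
    k: int = 100,
    null_reps: int = 1000,
    seed: int = 0,
    relevances: Mapping[CausalCategory, float] | None = None,
    restrict_to_known: bool = False,
    gene_names: Sequence[str] | None = None,
) -> EvaluationReport:
    """Full evaluation of a score matrix or ranking against a goldstandard."""
    if isinstance(scores, EdgeRanking):
        if gene_names is None:
            raise ValueError("gene_names is required to evaluate an EdgeRanking")
        min_score = min((s for _, _, s in scores), default=0.0)
        scores = ranking_to_matrix(scores, gene_names, fill=min(0.0, min_score) - 1.0)
    report = overall_score(
        scores, gold, tfs, null_reps=null_reps, seed=seed,
        restrict_to_known=restrict_to_known,
    )
    relevances = dict(DEFAULT_RELEVANCES if relevances is None else relevances)
    report.k = k
    report.relevances = relevances
    report.ndcg = ndcg_score(scores, gold, k, relevances)
    classifier = FalsePositiveClassifier(gold)
    counts = Counter(
        classifier.classify(i, j) for i, j in _ordered_pairs(scores, None)[:k]
    )
    counts.pop(CausalCategory.TRUE_POSITIVE, None)
    report.fp_category_counts = dict(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report.symmetry = matrix_symmetry(scores)
    return report
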