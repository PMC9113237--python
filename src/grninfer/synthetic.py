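"""Simulation of scale-free regulatory networks and steady-state expression.

Networks are sampled by preferential attachment among regulators over a
fixed topological order (regulators first), giving heavy-tailed out-degree
distributions and an acyclic graph by construction.  Expression follows a
linear-Gaussian structural equation model on the log scale,

    y = (I - W^T)^-1 (b + process noise [+ perturbation]),

with the latent log-expression saturated at +-:data:`LATENT_SATURATION`
(expression machinery saturates) and i.i.d. measurement noise added after
propagation:

    X = exp(clip(y) + measurement noise).

Observed values are therefore strictly positive with skewed (log-normal)
marginals and monotone gene-gene relationships.  Process noise is a small
fraction of the nominal noise level, so unperturbed wild-type rows carry
little network signal while multifactorial perturbations and knock-outs
carry a lot -- matching the relative information content of those
experiment classes on real benchmarks.  Knock-outs clamp the latent value
of the target gene to a low floor and propagate effects downstream,
emulating an intervention do(X_g ~= 0).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import Annotation, ExpressionDataset, GoldStandard, TFList

__all__ = [
    "SyntheticGRN",
    "sample_grn",
    "simulate_expression",
    "simulate_knockouts",
    "default_gene_names",
    "KO_LOG_FLOOR",
    "LATENT_SATURATION",
    "PROCESS_NOISE_FRACTION",
]

#: latent log-expression assigned to a knocked-out gene; low enough to kill
#: downstream signalling, finite so observed values stay positive
KO_LOG_FLOOR = -6.0

#: saturation bound on latent log-expression before observation
LATENT_SATURATION = 2.0

#: fraction of ``noise_sd`` that acts as process noise inside the network;
#: the remainder models per-measurement technical noise
PROCESS_NOISE_FRACTION = 0.25


def default_gene_names(m: int) -> list:
    width = max(3, len(str(m - 1)))
    return [f"G{i:0{width}d}" for i in range(m)]


@dataclasses.dataclass
class SyntheticGRN:
    """A known directed network with simulation parameters.

    ``adjacency[i, j]`` is the signed weight of the edge i -> j; genes are
    in topological order (an edge always points to a higher index) and the
    regulator set occupies the first indices.
    """

    adjacency: np.ndarray
    tf_set: frozenset
    basal: np.ndarray
    noise_sd: float
    seed: int

    def __post_init__(self):
        W = np.asarray(self.adjacency, dtype=float)
        if np.any(np.tril(W) != 0):
            raise ValueError("adjacency must be strictly upper-triangular (topological order)")
        regulators = set(np.nonzero(W.any(axis=1))[0].tolist())
        if not regulators <= set(self.tf_set):
            raise ValueError("every edge must originate from a regulator")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.adjacency = W
        self.basal = np.asarray(self.basal, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    @property
    def process_sd(self) -> float:
        return self.noise_sd * PROCESS_NOISE_FRACTION

    def gene_names(self) -> list:
        return default_gene_names(self.n_genes)

    def tf_list(self) -> TFList:
        return TFList(self.tf_set, self.n_genes)

    def goldstandard(self) -> GoldStandard:
        edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))}
        return GoldStandard(edges, self.n_genes)


def sample_grn(
    m: int,
    n_edges: int,
    tf_fraction: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> SyntheticGRN:
    """Sample a random acyclic scale-free network.

    Regulators are the first ``round(tf_fraction * m)`` genes of the
    topological order; each edge picks its regulator with probability
    proportional to the current out-degree plus a small offset
    (preferential attachment, heavy-tailed out-degrees) and a uniform
    random target further down the order.
    Edge weights are uniform on +-[0.5, 1.5] with a 25% chance of being
    negative.
    """
    if m < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    n_tfs = max(1, int(round(tf_fraction * m)))
    capacity = sum(m - 1 - t for t in range(n_tfs))
    if n_edges > capacity:
        raise ValueError(
            f"cannot place {n_edges} acyclic edges with {n_tfs} regulators "
            f"(capacity {capacity})"
        )

    W = np.zeros((m, m))
    out_degree = np.zeros(n_tfs)
    free = np.array([m - 1 - t for t in range(n_tfs)], dtype=float)
    for _ in range(n_edges):
        weights = (out_degree + 0.25) * (free > 0)
        t = int(rng.choice(n_tfs, p=weights / weights.sum()))
        candidates = np.nonzero(W[t, t + 1:] == 0)[0] + t + 1
        j = int(rng.choice(candidates))
        magnitude = rng.uniform(0.5, 1.5)
        sign = -1.0 if rng.random() < 0.25 else 1.0
        W[t, j] = sign * magnitude
        out_degree[t] += 1
        free[t] -= 1

    basal = rng.normal(0.0, 0.5, size=m)
    return SyntheticGRN(W, frozenset(range(n_tfs)), basal, noise_sd, seed)


def _propagate(grn: SyntheticGRN, drivers: np.ndarray) -> np.ndarray:
    """Saturated steady-state latent values for rows of driver terms."""
    m = grn.n_genes
    A = np.linalg.inv(np.eye(m) - grn.adjacency.T)
    return np.clip(drivers @ A.T, -LATENT_SATURATION, LATENT_SATURATION)


def simulate_expression(
    grn: SyntheticGRN,
    n_samples: int,
    mode: str = "multifactorial",
    seed: int = 0,
    perturb_sd: float = 1.0,
) -> ExpressionDataset:
    """Simulate steady-state expression for wild-type or perturbed samples.

    ``multifactorial`` mode perturbs every gene's basal rate independently
    per sample (standard deviation ``perturb_sd``); ``wild_type`` mode has
    process and measurement noise only.
    """
    if mode not in ("multifactorial", "wild_type"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    rng = np.random.default_rng(seed)
    m = grn.n_genes
    drivers = grn.basal[np.newaxis, :] + rng.normal(0, grn.process_sd, (n_samples, m))
    if mode == "multifactorial":
        drivers = drivers + rng.normal(0, perturb_sd, (n_samples, m))
    y = _propagate(grn, drivers) + rng.normal(0, grn.noise_sd, (n_samples, m))
    X = np.exp(y)
    kind = "other" if mode == "multifactorial" else "wild_type"
    annotations = [Annotation(kind)] * n_samples
    return ExpressionDataset(X, grn.gene_names(), annotations)


def simulate_knockouts(
    grn: SyntheticGRN,
    genes=None,
    seed: int = 0,
    replicates: int = 1,
) -> ExpressionDataset:
    """Simulate one (or more) single-gene knock-out rows per gene.

    The knocked-out gene's latent value is clamped to :data:`KO_LOG_FLOOR`
    and the structural equations are solved downstream in topological
    order, so only the gene itself and its descendants are systematically
    affected.
    """
    m = grn.n_genes
    if genes is None:
        genes = range(m)
    genes = [int(g) for g in genes]
    if any(g < 0 or g >= m for g in genes):
        raise ValueError("knock-out gene index out of range")
    rng = np.random.default_rng(seed)
    W = grn.adjacency
    rows = []
    annotations = []
    for g in genes:
        for _ in range(replicates):
            eps = rng.normal(0, grn.process_sd, m)
            y = np.empty(m)
            for j in range(m):  # genes are in topological order
                y[j] = grn.basal[j] + W[:j, j] @ y[:j] + eps[j]
                if j == g:
                    y[j] = KO_LOG_FLOOR
            y = np.clip(y, -LATENT_SATURATION, LATENT_SATURATION)
            rows.append(np.exp(y + rng.normal(0, grn.noise_sd, m)))
            annotations.append(Annotation("knockout", frozenset({g})))
    values = np.array(rows) if rows else np.empty((0, m))
    return ExpressionDataset(values, grn.gene_names(), annotations)
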