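"""Directional information on top of the symmetric Gaussian scores.

Three independent sources break the symmetry of the precision-based scores:

1. regression re-weighting: each score is multiplied by
   ``|B[i, j]| / max(|B[i, j]|, |B[j, i]|)`` where ``B[i, j]`` is the
   coefficient of gene ``i`` in the least-squares prediction of gene ``j``
   from all other genes.  All ``m`` regressions come from the precision
   matrix in closed form, ``B[i, j] = -theta[i, j] / theta[j, j]``, in a
   single pass;
2. null-mutant Z-scores from single-gene knock-out experiments, fused
   multiplicatively after L2 normalization and elementwise squaring;
3. a hub-emphasizing post-processing that multiplies each row by the
   standard deviation of its off-diagonal entries.

The regulatory sign is read off the precision matrix.  The end-to-end
entry point is :func:`infer_network`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .data_io import ExpressionDataset, TFList
from .gaussian_core import (
    DEFAULT_ALPHA,
    ZERO_TOL,
    CorrectedMatrix,
    CovarianceEstimate,
    PrecisionMatrix,
    correct_precision,
    sample_covariance,
    shrink_and_invert,
)
from .preprocess import PowerTransformParams, apply_power_transform, fit_power_transform

__all__ = [
    "SIGN_CONVENTIONS",
    "InferenceConfig",
    "RegressionWeights",
    "ZScoreMatrix",
    "FinalScores",
    "InferenceResult",
    "compute_regression_weights",
    "apply_regression_reweighting",
    "compute_ko_zscores",
    "ko_zscore_scores",
    "fuse_scores",
    "hub_postprocess",
    "extract_signs",
    "infer_network",
]

SIGN_CONVENTIONS = ("precision", "partial-correlation")


@dataclasses.dataclass
class InferenceConfig:
    """Stage toggles and numeric parameters of the inference pipeline."""

    alpha: float = DEFAULT_ALPHA
    use_ko: bool = True
    use_regression_weights: bool = True
    use_hub_postprocess: bool = True
    sign_convention: str = "precision"
    zero_tol: float = ZERO_TOL

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ValueError(
                f"sign_convention must be one of {SIGN_CONVENTIONS}, "
                f"got {self.sign_convention!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RegressionWeights:
    """Closed-form multiple-regression coefficients, one column per target."""

    B: np.ndarray


@dataclasses.dataclass
class ZScoreMatrix:
    """Per-(knocked-out gene, target) deviation scores.

    ``Z[i, j]`` measures how far target ``j`` moved after the knock-out of
    gene ``i``, in standard-deviation units of ``j`` across all single-KO
    experiments.  Rows of genes without a knock-out hold the median
    fallback ``z_bar``; the diagonal is zeroed (a KO trivially changes the
    knocked-out gene itself).
    """

    Z: np.ndarray
    z_bar: float
    mu: np.ndarray
    sigma: np.ndarray
    ko_genes: frozenset


@dataclasses.dataclass
class FinalScores:
    """Asymmetric confidence matrix and regulatory signs."""

    M_bar: np.ndarray
    sign: np.ndarray


@dataclasses.dataclass
class InferenceResult:
    """All pipeline intermediates, retrievable for testing and diagnostics."""

    gene_names: list
    tfs: TFList
    config: InferenceConfig
    transform_params: PowerTransformParams
    transformed: np.ndarray
    covariance: CovarianceEstimate
    precision: PrecisionMatrix
    corrected: CorrectedMatrix
    regression: RegressionWeights | None
    zscores: ZScoreMatrix | None
    scores: FinalScores

    @property
    def M_bar(self) -> np.ndarray:
        return self.scores.M_bar

    @property
    def sign(self) -> np.ndarray:
        return self.scores.sign


# ---------------------------------------------------------------------------
# regression re-weighting


def compute_regression_weights(theta: PrecisionMatrix | np.ndarray) -> RegressionWeights:
    """All m least-squares regressions in one pass over the precision matrix.

    Under the shrunk Gaussian model the coefficient of gene ``i`` in the
    regression of gene ``j`` on all other genes is
    ``B[i, j] = -theta[i, j] / theta[j, j]``, identical to solving the m
    normal-equation systems on the shrunk moments.
    """
    T = theta.theta if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    d = np.diag(T)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    B = -T / d[np.newaxis, :]
    np.fill_diagonal(B, 0.0)
    return RegressionWeights(B)


def apply_regression_reweighting(
    M: CorrectedMatrix | np.ndarray, weights: RegressionWeights, tol: float = ZERO_TOL
) -> np.ndarray:
    """Scale each score by ``|B_ij| / max(|B_ij|, |B_ji|)``.

    Pairs where both coefficients are (numerically) zero carry no
    directional information and are left unchanged.
    """
    scores = M.M if isinstance(M, CorrectedMatrix) else np.asarray(M, float)
    A = np.abs(weights.B)
    denom = np.maximum(A, A.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > tol, A / np.where(denom > tol, denom, 1.0), 1.0)
    return scores * w


# ---------------------------------------------------------------------------
# knock-out Z-scores


def compute_ko_zscores(data: ExpressionDataset) -> ZScoreMatrix | None:
    """Null-mutant Z-scores from single-gene knock-out experiments.

    Multi-gene knock-outs are discarded (the knocked-out genes would act as
    confounders).  For each single-KO row of gene ``i``,
    ``Z[i, j] = |x[j] - mu[j]| / sigma[j]`` with ``mu`` / ``sigma`` taken
    across all single-KO rows; replicate knock-outs of the same gene are
    averaged.  Rows of genes never knocked out are filled with the median of
    all computed scores.  Returns ``None`` (the no-KO sentinel) when fewer
    than two single-KO rows are available.
    """
    rows = [
        (r, next(iter(ann.genes)))
        for r, ann in enumerate(data.annotations)
        if ann.is_single_knockout
    ]
    if len(rows) < 2:
        return None
    m = data.n_genes
    X_ko = data.values[[r for r, _ in rows], :]
    mu = X_ko.mean(axis=0)
    sigma = X_ko.std(axis=0, ddof=1)
    degenerate = sigma <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} target(s) with zero variance across KO "
            "experiments: their Z entries are set to 0",
            stacklevel=2,
        )
    safe_sigma = np.where(degenerate, 1.0, sigma)

    sums = np.zeros((m, m))
    counts = np.zeros(m)
    for row, gene in zip(X_ko, (g for _, g in rows)):
        z = np.abs(row - mu) / safe_sigma
        z[degenerate] = 0.0
        sums[gene] += z
        counts[gene] += 1
    ko_genes = counts > 0
    Z = np.zeros((m, m))
    Z[ko_genes] = sums[ko_genes] / counts[ko_genes, np.newaxis]

    offdiag = ~np.eye(m, dtype=bool)
    z_bar = float(np.median(Z[ko_genes][offdiag[ko_genes]]))
    Z[~ko_genes] = z_bar
    np.fill_diagonal(Z, 0.0)
    return ZScoreMatrix(
        Z, z_bar, mu, sigma, frozenset(int(g) for g in np.nonzero(ko_genes)[0])
    )


def ko_zscore_scores(data: ExpressionDataset, tfs: TFList | None = None) -> np.ndarray | None:
    """Standalone Z-score scorer (the knock-out-only baseline method).

    Returns a ranking-ready matrix with non-regulator rows zeroed, or
    ``None`` when no usable knock-out data is present.
    """
    zs = compute_ko_zscores(data)
    if zs is None:
        return None
    scores = zs.Z.copy()
    if tfs is not None:
        scores[~tfs.mask(), :] = 0.0
    np.fill_diagonal(scores, 0.0)
    return scores


# ---------------------------------------------------------------------------
# fusion, post-processing, signs


def fuse_scores(M: np.ndarray, zscores: ZScoreMatrix | None) -> np.ndarray:
    """Fuse observational scores with interventional Z-scores.

    ``Z`` is L2-normalized over its off-diagonal entries then squared
    elementwise (emphasizing the top interventional scores), and the fused
    matrix is the elementwise product ``M * Z**2``.  With the no-KO
    sentinel the fusion is the identity.
    """
    M = np.asarray(M, dtype=float)
    if zscores is None:
        return M.copy()
    Z = zscores.Z
    offdiag = ~np.eye(Z.shape[0], dtype=bool)
    norm = float(np.linalg.norm(Z[offdiag]))
    if norm <= 0:
        warnings.warn("all Z-scores are zero: skipping fusion", stacklevel=2)
        return M.copy()
    return M * (Z / norm) ** 2


def hub_postprocess(M_bar: np.ndarray) -> np.ndarray:
    """Multiply each row by the standard deviation of its off-diagonal part.

    Row dispersion proxies the out-degree centrality of a regulator, letting
    hub rows stand out of the background.
    """
    M_bar = np.asarray(M_bar, dtype=float)
    m = M_bar.shape[0]
    offdiag = ~np.eye(m, dtype=bool)
    stds = np.array([M_bar[i, offdiag[i]].std() for i in range(m)])
    return M_bar * stds[:, np.newaxis]


def extract_signs(
    theta: PrecisionMatrix | np.ndarray,
    M_bar: np.ndarray,
    convention: str = "precision",
) -> np.ndarray:
    """Regulatory signs, non-zero exactly where the final scores are.

    The default reports the sign of the precision entry; the
    ``partial-correlation`` convention flips it (the partial correlation is
    ``-theta_ij / sqrt(theta_ii * theta_jj)``).
    """
    if convention not in SIGN_CONVENTIONS:
        raise ValueError(f"unknown sign convention {convention!r}")
    T = theta.theta if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    sign = np.sign(T) * (np.asarray(M_bar) > 0)
    if convention == "partial-correlation":
        sign = -sign
    return sign.astype(int)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _strip_knockouts(data: ExpressionDataset) -> ExpressionDataset:
    keep = [r for r, ann in enumerate(data.annotations)
            if ann.kind not in ("knockout", "knockdown")]
    if len(keep) == data.n_experiments:
        return data
    return ExpressionDataset(
        data.values[keep], data.gene_names, [data.annotations[r] for r in keep]
    )


def infer_network(
    data: ExpressionDataset,
    tfs: TFList | None = None,
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Run the full inference pipeline on one expression dataset.

    Stages: per-gene power transform, sample covariance, shrinkage
    inversion, bias correction with TF masking, regression re-weighting,
    knock-out Z-score fusion, hub post-processing and sign extraction.
    Every intermediate is kept on the returned :class:`InferenceResult`.

    With ``config.use_ko`` disabled the knock-out/knock-down rows are
    removed from the dataset up front, mirroring interventional-data
    ablation experiments.
    """
    config = config or InferenceConfig()
    if tfs is None:
        tfs = TFList.all_genes(data.n_genes)
    if tfs.n_genes != data.n_genes:
        raise ValueError("TF list does not match the dataset's gene count")

    if not config.use_ko:
        data = _strip_knockouts(data)

    params = fit_power_transform(data)
    Y = apply_power_transform(data, params)
    est = sample_covariance(Y)
    theta = shrink_and_invert(est, config.alpha)
    corrected = correct_precision(theta, tfs, config.zero_tol)

    M = corrected.M
    regression = None
    if config.use_regression_weights:
        regression = compute_regression_weights(theta)
        M = apply_regression_reweighting(M, regression, config.zero_tol)

    zscores = compute_ko_zscores(data) if config.use_ko else None
    M_bar = fuse_scores(M, zscores)

    if config.use_hub_postprocess:
        M_bar = hub_postprocess(M_bar)

    sign = extract_signs(theta, M_bar, config.sign_convention)
    return InferenceResult(
        gene_names=list(data.gene_names),
        tfs=tfs,
        config=config,
        transform_params=params,
        transformed=Y,
        covariance=est,
        precision=theta,
        corrected=corrected,
        regression=regression,
        zscores=zscores,
        scores=FinalScores(M_bar, sign),
    )
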