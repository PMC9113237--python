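"""Covariance estimation, shrinkage inversion and bias correction.

The sample covariance of the transformed data is shrunk towards its own
diagonal, ``S_bar = alpha * diag(S) + (1 - alpha) * S``, which guarantees a
well-conditioned matrix for sufficiently large ``alpha`` even when there are
fewer samples than genes.  Its inverse (the precision matrix) encodes
conditional independence: a zero off-diagonal entry means the two genes are
independent given all others.  A multiplicative row-column weighting then
removes gene-specific biases while preserving exact zeros, and rows of genes
not eligible as regulators are masked out.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

from .data_io import TFList

__all__ = [
    "DEFAULT_ALPHA",
    "ZERO_TOL",
    "SingularityError",
    "CovarianceEstimate",
    "PrecisionMatrix",
    "CorrectedMatrix",
    "sample_covariance",
    "shrink_and_invert",
    "correct_precision",
    "write_matrix_tsv",
]

#: shrinkage coefficient used in all experiments unless overridden
DEFAULT_ALPHA = 0.8

#: entries with absolute value below this are treated as exact zeros, both
#: for the non-zero means in the correction and for zero-preservation
ZERO_TOL = 1e-12


class SingularityError(ValueError):
    """The (shrunk) covariance cannot be inverted."""


@dataclasses.dataclass
class CovarianceEstimate:
    """Sample covariance ``S`` with its diagonal and optional shrunk form."""

    S: np.ndarray
    D: np.ndarray
    n_samples: int
    alpha: float | None = None
    S_bar: np.ndarray | None = None
    zero_variance: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.S.shape[0]


@dataclasses.dataclass
class PrecisionMatrix:
    """Symmetric inverse of the shrunk covariance."""

    theta: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.theta.shape[0]


@dataclasses.dataclass
class CorrectedMatrix:
    """Non-negative score matrix after bias correction and TF masking."""

    M: np.ndarray
    tfs: TFList


def sample_covariance(Y: np.ndarray) -> CovarianceEstimate:
    """Column-centered sample covariance with the n-1 denominator.

    Zero-variance columns are permitted but flagged, since they break
    invertibility downstream.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate a covariance")
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    S = (Yc.T @ Yc) / (n - 1)
    S = (S + S.T) / 2.0
    D = np.diag(S).copy()
    zero_variance = D <= ZERO_TOL
    if zero_variance.any():
        warnings.warn(
            f"{int(zero_variance.sum())} zero-variance column(s) in covariance",
            stacklevel=2,
        )
    return CovarianceEstimate(S, D, n, zero_variance=zero_variance)


def shrink_and_invert(est: CovarianceEstimate, alpha: float = DEFAULT_ALPHA) -> PrecisionMatrix:
    """Form the shrunk covariance and invert it via a Cholesky factorization.

    ``S_bar = alpha * diag(S) + (1 - alpha) * S`` keeps the diagonal of ``S``
    untouched and has smallest eigenvalue at least ``alpha * min_j D_jj``, so
    the inversion succeeds whenever every gene has positive variance.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if np.any(est.D <= 0):
        j = int(np.argmax(est.D <= 0))
        raise SingularityError(
            f"gene {j} has zero variance: shrunk covariance is singular"
        )
    S_bar = (1.0 - alpha) * est.S
    np.fill_diagonal(S_bar, est.D)
    est.alpha = alpha
    est.S_bar = S_bar
    try:
        cho = linalg.cho_factor(S_bar, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularityError(f"shrunk covariance is not positive definite: {exc}")
    theta = linalg.cho_solve(cho, np.eye(S_bar.shape[0]), check_finite=False)
    theta = (theta + theta.T) / 2.0
    return PrecisionMatrix(theta)


def correct_precision(
    theta: PrecisionMatrix | np.ndarray,
    tfs: TFList | None = None,
    zero_tol: float = ZERO_TOL,
) -> CorrectedMatrix:
    """Multiplicative row-column weighting of the precision matrix.

    ``M[i, j] = 2 |theta[i, j]| / (mu_row[i] * mu_col[j])`` for regulators
    ``i`` in the TF list and zero otherwise, where ``mu_row[i]`` is the mean
    of the non-zero absolute off-diagonal entries of row ``i`` and
    ``mu_col[j]`` the same over column ``j`` restricted to TF rows.  Exact
    zeros of the precision matrix stay zero, preserving the conditional
    independence structure; the diagonal is excluded from the means and
    zeroed in the result.
    """
    T = theta.theta if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    if not np.all(np.isfinite(T)):
        raise ValueError("precision matrix contains non-finite entries")
    m = T.shape[0]
    if tfs is None:
        tfs = TFList.all_genes(m)
    tf_mask = tfs.mask()

    A = np.abs(T)
    offdiag = ~np.eye(m, dtype=bool)
    nonzero = (A > zero_tol) & offdiag

    with np.errstate(invalid="ignore", divide="ignore"):
        row_counts = nonzero.sum(axis=1)
        mu_row = np.where(row_counts > 0, (A * nonzero).sum(axis=1) / row_counts, np.nan)
        col_admissible = nonzero & tf_mask[:, np.newaxis]
        col_counts = col_admissible.sum(axis=0)
        mu_col = np.where(col_counts > 0, (A * col_admissible).sum(axis=0) / col_counts, np.nan)

        M = 2.0 * A / (mu_row[:, np.newaxis] * mu_col[np.newaxis, :])

    undefined = ~np.isfinite(M)
    if np.any(undefined & nonzero & tf_mask[:, np.newaxis]):
        warnings.warn(
            "undefined row/column mean in correction: affected entries set to 0",
            stacklevel=2,
        )
    M[undefined] = 0.0
    M[~nonzero] = 0.0
    M[~tf_mask, :] = 0.0
    np.fill_diagonal(M, 0.0)
    return CorrectedMatrix(M, tfs)


def write_matrix_tsv(matrix: np.ndarray, gene_names, path) -> None:
    """Dump a genes x genes matrix with a header row/column for inspection."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(gene_names) + "\n")
        for name, row in zip(gene_names, matrix):
            fh.write(name + "\t" + "\t".join("%.17g" % v for v in row) + "\n")
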