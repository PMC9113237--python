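"""Per-gene power transforms that make skewed expression data more Gaussian.

Each column is transformed independently with the Box-Cox family

    y = (x**lam - 1) / lam    (lam != 0)
    y = log(x)                (lam == 0)

with ``lam`` chosen per gene by maximizing the profile log-likelihood.
Columns containing zeros receive a small positive shift beforehand so the
transform is defined; the shift is 1% of the smallest positive value in the
column, which preserves the sample ordering with minimal distortion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special, stats

from .data_io import ExpressionDataset, ExpressionDomainError

__all__ = ["PowerTransformParams", "fit_power_transform", "apply_power_transform",
           "write_transform_params"]

#: bounded search interval for the transform exponent
LAMBDA_BOUNDS = (-5.0, 5.0)
#: absolute tolerance of the exponent optimization
LAMBDA_XATOL = 1e-5


@dataclasses.dataclass
class PowerTransformParams:
    """Fitted per-gene transform parameters.

    Attributes
    ----------
    lambdas:
        One exponent per gene.
    shifts:
        Non-negative offset added to each column before transforming;
        strictly positive whenever the column contains a zero.
    degenerate:
        Boolean flag per gene marking (near-)constant columns, for which
        the exponent is fixed at 1.
    """

    lambdas: np.ndarray
    shifts: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (len(self.lambdas) == len(self.shifts) == len(self.degenerate)):
            raise ValueError("parameter vectors must have equal length")
        if np.any(self.shifts < 0):
            raise ValueError("shifts must be non-negative")


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, ExpressionDataset):
        return data.values
    return np.asarray(data, dtype=float)


def _column_shift(column: np.ndarray) -> float:
    if column.min() > 0:
        return 0.0
    positive = column[column > 0]
    # all-zero columns are degenerate anyway; any positive shift will do
    return float(positive.min()) * 1e-2 if positive.size else 1e-2


def fit_power_transform(data) -> PowerTransformParams:
    """Fit one Box-Cox exponent per gene by maximum likelihood.

    The profile log-likelihood is maximized over ``lam`` in
    :data:`LAMBDA_BOUNDS` by bounded scalar optimization (deterministic).
    Degenerate (constant) columns are flagged and assigned ``lam = 1``.
    """
    X = _as_matrix(data)
    m = X.shape[1]
    lambdas = np.ones(m)
    shifts = np.zeros(m)
    degenerate = np.zeros(m, dtype=bool)
    for j in range(m):
        column = X[:, j]
        shifts[j] = _column_shift(column)
        x = column + shifts[j]
        if x.size < 2 or np.ptp(x) < 1e-12 * max(1.0, abs(x[0])):
            degenerate[j] = True
            continue
        res = optimize.minimize_scalar(
            lambda lam: -stats.boxcox_llf(lam, x),
            bounds=LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": LAMBDA_XATOL},
        )
        lambdas[j] = float(res.x)
    return PowerTransformParams(lambdas, shifts, degenerate)


def apply_power_transform(data, params: PowerTransformParams) -> np.ndarray:
    """Apply fitted per-gene transforms; returns the transformed matrix.

    Raises
    ------
    ExpressionDomainError
        If a shifted value is not strictly positive (names gene and row).
    """
    X = _as_matrix(data)
    if X.shape[1] != len(params.lambdas):
        raise ValueError("parameter count does not match gene count")
    shifted = X + params.shifts[np.newaxis, :]
    if np.any(shifted <= 0):
        r, j = np.argwhere(shifted <= 0)[0]
        name = data.gene_names[j] if isinstance(data, ExpressionDataset) else str(j)
        raise ExpressionDomainError(
            f"non-positive shifted value at row {r}, gene {name}: "
            "power transform requires strictly positive input"
        )
    Y = np.empty_like(shifted)
    for j in range(shifted.shape[1]):
        Y[:, j] = special.boxcox(shifted[:, j], params.lambdas[j])
    return Y


def write_transform_params(params: PowerTransformParams, gene_names, path) -> None:
    """Dump fitted parameters as a provenance TSV (gene, lambda, shift)."""
    with open(path, "w") as fh:
        fh.write("gene\tlambda\tshift\tdegenerate\n")
        for g, lam, sh, deg in zip(gene_names, params.lambdas, params.shifts,
                                   params.degenerate):
            fh.write(f"{g}\t{lam:.17g}\t{sh:.17g}\t{int(deg)}\n")
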