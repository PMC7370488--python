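"""Matrix-factorization imputation of incomplete distance matrices.

The N x N distance matrix R is approximated as the product of two latent
factor matrices, R ~ X Y^T with X, Y both N x K, fitted by regularized
stochastic gradient descent over the *observed* lower-triangular entries
only (R is symmetric, so the lower triangle carries all information).  A
missing distance is then predicted as the inner product

    r_hat(i, j) = sum_k x[i, k] * y[j, k]

For one observed entry with error e = r - r_hat, the update rules are

    x[i, k] <- x[i, k] + alpha * (2 e y[j, k] - beta x[i, k])
    y[j, k] <- y[j, k] + alpha * (2 e x[i, k] - beta y[j, k])

i.e. a gradient step on the squared error (r - r_hat)^2 plus an L2 penalty
(beta/2)(||x_i||^2 + ||y_j||^2); e is computed once per entry and both
updates use the pre-update coordinates.  Training sweeps the observed
entries in fixed row-major order and stops when the total squared error E
over one epoch drops below ``tol`` or after ``max_iter`` epochs.

Defaults: K = N latent features, alpha = 0.002, beta = 0.02, tol = 1e-6,
10,000 epochs.  Initialization is Uniform[0, 1) from an explicit seed, so
runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .matrix import MaskedDistanceMatrix

__all__ = ["MFConfig", "FactorPair", "mf_predict", "mf_update_entry", "mf_train", "mf_impute"]


class MFDivergenceError(RuntimeError):
    """Training error became non-finite or exceeded the divergence cap."""


_DIVERGENCE_CAP = 1e12


@dataclass(frozen=True)
class MFConfig:
    """Hyperparameters for matrix-factorization imputation.

    ``k=None`` means K = N (full-rank factorization), the default used
    throughout the package.
    """

    k: Optional[int] = None
    alpha: float = 0.002
    beta: float = 0.02
    max_iter: int = 10_000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FactorPair:
    """Latent factors X, Y (both N x K) plus the per-epoch error trace."""

    x: np.ndarray
    y: np.ndarray
    error_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.error_trace)


def mf_predict(f: FactorPair, i: int, j: int) -> float:
    """Imputed distance r_hat(i, j) = sum_k x[i, k] y[j, k]."""
    return float(f.x[i] @ f.y[j])


def mf_update_entry(
    f: FactorPair, i: int, j: int, r_ij: float, cfg: MFConfig
) -> FactorPair:
    """One SGD update on a single observed entry; returns a new FactorPair.

    The error e is computed once from the current factors and both the
    x-row and y-row updates use the pre-update coordinates.
    """
    if not i > j:
        raise ValueError("updates operate on the lower triangle: need i > j")
    x, y = f.x.copy(), f.y.copy()
    e = r_ij - float(x[i] @ y[j])
    xi, yj = x[i].copy(), y[j].copy()
    x[i] = xi + cfg.alpha * (2.0 * e * yj - cfg.beta * xi)
    y[j] = yj + cfg.alpha * (2.0 * e * xi - cfg.beta * yj)
    if not (np.all(np.isfinite(x[i])) and np.all(np.isfinite(y[j]))):
        raise MFDivergenceError(f"non-finite factors at entry ({i},{j})")
    return replace(f, x=x, y=y)


@njit(cache=True)
def _sgd_epochs(x, y, rows, cols, vals, alpha, beta, max_iter, tol, cap):
    """Row-major SGD sweeps; returns (trace, epochs_run, diverged_flag)."""
    n_entries = rows.shape[0]
    k = x.shape[1]
    trace = np.empty(max_iter)
    for epoch in range(max_iter):
        total = 0.0
        for t in range(n_entries):
            i = rows[t]
            j = cols[t]
            pred = 0.0
            for kk in range(k):
                pred += x[i, kk] * y[j, kk]
            e = vals[t] - pred
            total += e * e
            for kk in range(k):
                xi = x[i, kk]
                yj = y[j, kk]
                x[i, kk] = xi + alpha * (2.0 * e * yj - beta * xi)
                y[j, kk] = yj + alpha * (2.0 * e * xi - beta * yj)
        trace[epoch] = total
        if not np.isfinite(total) or total > cap:
            return trace[: epoch + 1], epoch + 1, 1
        if total < tol:
            return trace[: epoch + 1], epoch + 1, 0
    return trace, max_iter, 0


def mf_train(m: MaskedDistanceMatrix, cfg: MFConfig = MFConfig()) -> FactorPair:
    """Fit the factor pair to the observed lower-triangular entries.

    X and Y are initialized Uniform[0, 1) from ``cfg.seed``.  One epoch is
    one pass over all observed entries (i, j), i > j, in row-major order.
    Raises :class:`MFDivergenceError` if the total error blows up.
    """
    pairs = list(m.observed_pairs())
    if not pairs:
        raise ValueError("matrix has no observed off-diagonal entries")
    n = m.n_taxa
    k = cfg.k if cfg.k is not None else n
    rng = np.random.default_rng(cfg.seed)
    x = rng.random((n, k))
    y = rng.random((n, k))
    rows = np.array([p[0] for p in pairs], dtype=np.int64)
    cols = np.array([p[1] for p in pairs], dtype=np.int64)
    vals = m.values[rows, cols]
    trace, epochs, diverged = _sgd_epochs(
        x, y, rows, cols, vals, cfg.alpha, cfg.beta, cfg.max_iter, cfg.tol, _DIVERGENCE_CAP
    )
    if diverged:
        raise MFDivergenceError(
            f"total error {trace[-1]!r} after {epochs} epochs (alpha={cfg.alpha}, "
            f"beta={cfg.beta}, k={k}, seed={cfg.seed})"
        )
    return FactorPair(x, y, np.asarray(trace), converged=bool(trace[-1] < cfg.tol))


def mf_impute_with_factors(
    m: MaskedDistanceMatrix, cfg: MFConfig = MFConfig()
) -> tuple[MaskedDistanceMatrix, Optional[FactorPair]]:
    """Impute and also return the trained factors (``None`` if no training
    was needed because the input was already complete)."""
    if m.is_complete:
        return m.copy(), None
    f = mf_train(m, cfg)
    values = m.values.copy()
    for i, j in m.missing_pairs():
        pred = max(0.0, mf_predict(f, i, j))
        values[i, j] = values[j, i] = pred
    np.fill_diagonal(values, 0.0)
    return MaskedDistanceMatrix(m.labels, values), f


def mf_impute(
    m: MaskedDistanceMatrix, cfg: MFConfig = MFConfig()
) -> MaskedDistanceMatrix:
    """Return a complete matrix: observed entries verbatim, missing filled.

    Each missing pair (i, j), i > j, is filled with max(0, r_hat(i, j)) and
    mirrored; the mask of the result is empty.  A complete input is
    returned unchanged (no training).
    """
    return mf_impute_with_factors(m, cfg)[0]
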