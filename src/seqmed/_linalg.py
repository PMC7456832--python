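"""Thin least-squares helpers used by every estimation stage.

All estimators in this package reduce to small ordinary or weighted
least-squares fits that are re-run hundreds of thousands of times inside
Monte Carlo and bootstrap loops, so the fits are done directly with
``numpy.linalg.lstsq`` on explicit design matrices.
"""

from __future__ import annotations

import numpy as np


class DegenerateDesignError(ValueError):
    """Raised when the regression design matrix is rank-deficient."""


def ols(y: np.ndarray, columns: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Least squares of ``y`` on an intercept plus the given columns.

    Returns ``(coefs, residual_sd)`` where ``coefs[0]`` is the intercept and
    ``residual_sd`` is the classical residual standard error
    ``sqrt(RSS / (n - p))``.
    """
    n = y.shape[0]
    X = np.column_stack([np.ones(n), *columns])
    p = X.shape[1]
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise DegenerateDesignError(
            f"design matrix is rank deficient (rank {rank} < {p} columns)"
        )
    resid = y - X @ coefs
    dof = n - p
    if dof <= 0:
        raise DegenerateDesignError(f"no residual degrees of freedom (n={n}, p={p})")
    residual_sd = float(np.sqrt(resid @ resid / dof))
    return coefs, residual_sd


def wls(y: np.ndarray, columns: list[np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Weighted least squares via the sqrt-weight transform; returns coefs."""
    w = np.sqrt(weights)
    n = y.shape[0]
    X = np.column_stack([np.ones(n), *columns]) * w[:, None]
    coefs, _, rank, _ = np.linalg.lstsq(X, y * w, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"weighted design matrix is rank deficient (rank {rank})"
        )
    return coefs
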