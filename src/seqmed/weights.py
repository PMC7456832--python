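"""Mediator propensity models and stabilized inverse-propensity weights.

For a continuous mediator the "propensity score" is a conditional normal
density: the mediator is regressed on treatment plus confounders, and the
density phi(M | X, C) is evaluated at each record's observed M using that
model's fitted value and residual standard error.  The stabilized weight is
the ratio of a treatment-only numerator density to the full denominator
density,

    w_i = phi(M_i | X_i) / phi(M_i | X_i, C_i),

so the weights reflect only the additional prediction contributed by the
confounders.  A binary-mediator analogue uses fitted probabilities from
logistic models in place of densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import ols

__all__ = [
    "PropensitySpec",
    "DensityModelFit",
    "DegenerateModelError",
    "PositivityError",
    "compute_mediator_weights",
    "compute_binary_mediator_weights",
    "truncate_weights",
    "nearest_rank_percentile",
    "weight_diagnostics_frame",
]


class DegenerateModelError(ValueError):
    """Mediator model fits perfectly; the propensity density is degenerate."""


class PositivityError(ValueError):
    """A fitted probability of 0 or 1 makes a weight undefined."""


@dataclass(frozen=True)
class PropensitySpec:
    """Which confounders enter the denominator mediator model.

    The numerator model always regresses the mediator on treatment alone;
    the denominator adds ``denominator_covariates``.
    """

    mediator_kind: str = "continuous"
    denominator_covariates: tuple[str, ...] = field(default_factory=tuple)
    mediator: str = "M"
    treatment: str = "X"

    def __post_init__(self) -> None:
        if self.mediator_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown mediator_kind {self.mediator_kind!r}")


@dataclass(frozen=True)
class DensityModelFit:
    """Fitted mediator model: coefficients and residual SD (continuous case)."""

    coefficients: np.ndarray
    residual_sd: float
    fitted: np.ndarray


def _fit_mediator_model(data: pd.DataFrame, mediator: str, treatment: str,
                        covariates: tuple[str, ...]) -> DensityModelFit:
    y = data[mediator].to_numpy(dtype=float)
    cols = [data[treatment].to_numpy(dtype=float)]
    cols += [data[c].to_numpy(dtype=float) for c in covariates]
    coefs, sd = ols(y, cols)
    # a residual SD at rounding-error scale relative to the spread of M is a
    # perfect fit, for which the propensity density is degenerate
    if not math.isfinite(sd) or sd <= 1e-8 * max(float(np.std(y)), 1e-300):
        raise DegenerateModelError(
            "mediator model has zero residual standard error (perfect fit)"
        )
    n = len(y)
    X = np.column_stack([np.ones(n), *cols])
    return DensityModelFit(coefficients=coefs, residual_sd=sd, fitted=X @ coefs)


def compute_mediator_weights(data: pd.DataFrame, spec: PropensitySpec) -> np.ndarray:
    """Stabilized density-ratio weights for a continuous mediator.

    Both models are ordinary least squares of M; each normal density is
    evaluated at the observed M with that model's fitted value and residual
    standard error.  With no denominator covariates the two models coincide
    and every weight is exactly 1.
    """
    missing = [c for c in spec.denominator_covariates if c not in data.columns]
    if missing:
        raise KeyError(f"covariates not in dataset: {missing}")
    if len(data) < len(spec.denominator_covariates) + 3:
        raise ValueError("too few records to fit the mediator models")
    m = data[spec.mediator].to_numpy(dtype=float)
    num = _fit_mediator_model(data, spec.mediator, spec.treatment, ())
    if not spec.denominator_covariates:
        return np.ones(len(data))
    den = _fit_mediator_model(data, spec.mediator, spec.treatment,
                              tuple(spec.denominator_covariates))
    num_density = stats.norm.pdf(m, loc=num.fitted, scale=num.residual_sd)
    den_density = stats.norm.pdf(m, loc=den.fitted, scale=den.residual_sd)
    with np.errstate(divide="raise", invalid="raise"):
        try:
            w = num_density / den_density
        except FloatingPointError as exc:
            bad = int(np.argmin(den_density))
            raise FloatingPointError(
                f"non-finite weight at record {bad} "
                f"(denominator density {den_density[bad]:.3g})"
            ) from exc
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        bad = int(np.argmax(~(np.isfinite(w) & (w > 0))))
        raise FloatingPointError(f"non-finite or non-positive weight at record {bad}")
    return w


def compute_binary_mediator_weights(data: pd.DataFrame,
                                    spec: PropensitySpec) -> np.ndarray:
    """Stabilized probability-ratio weights for a 0/1 mediator.

    Records with M = 1 get P[M=1|X] / P[M=1|X,C]; records with M = 0 get
    the complement ratio.  Logistic regressions supply the probabilities.
    """
    import statsmodels.api as sm

    m = data[spec.mediator].to_numpy(dtype=float)
    if not np.all(np.isin(m, (0.0, 1.0))):
        raise ValueError("binary mediator must contain only 0 and 1")
    x = data[spec.treatment].to_numpy(dtype=float)
    X_num = sm.add_constant(x)
    p_num = sm.Logit(m, X_num).fit(disp=0).predict(X_num)
    if spec.denominator_covariates:
        X_den = sm.add_constant(np.column_stack(
            [x] + [data[c].to_numpy(dtype=float) for c in spec.denominator_covariates]
        ))
        p_den = sm.Logit(m, X_den).fit(disp=0).predict(X_den)
    else:
        p_den = p_num
    eps = np.finfo(float).tiny
    if np.any(p_den <= eps) or np.any(p_den >= 1 - 1e-12):
        raise PositivityError("fitted denominator probability of 0 or 1")
    w = np.where(m == 1.0, p_num / p_den, (1 - p_num) / (1 - p_den))
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise PositivityError("non-finite or non-positive binary-mediator weight")
    return w


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank empirical percentile: value at rank ceil(pct/100 * n)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(v[min(rank, n) - 1])


def truncate_weights(weights: np.ndarray, lower_pct: float = 1.0,
                     upper_pct: float = 99.0) -> np.ndarray:
    """Winsorize a weight vector at nearest-rank percentile caps.

    Caps come from the vector itself (not pooled across replications);
    order is preserved and the operation is idempotent.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weight vector is empty")
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    lo = nearest_rank_percentile(w, lower_pct)
    hi = nearest_rank_percentile(w, upper_pct)
    return np.clip(w, lo, hi)


def weight_diagnostics_frame(weights: np.ndarray,
                             truncated: np.ndarray) -> pd.DataFrame:
    """Per-record diagnostic table: record_index, weight, weight_truncated."""
    return pd.DataFrame({
        "record_index": np.arange(len(weights)),
        "weight": np.asarray(weights, dtype=float),
        "weight_truncated": np.asarray(truncated, dtype=float),
    })
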