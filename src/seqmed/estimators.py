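"""Five estimators of total, controlled direct, and indirect effects.

All estimators share the same total-effect estimate (the unadjusted
least-squares slope of Y on X, valid because treatment is randomized) and
report the indirect effect as the difference

    indirect = total - direct,

so the methods differ only through their controlled-direct-effect (CDE)
estimate:

* ``regression`` — OLS of Y on X, M and the chosen confounders; the X
  coefficient is the CDE.
* ``ipw`` / ``ipw_truncated`` — weighted least squares of Y on X and M only,
  using stabilized mediator-propensity weights (optionally winsorized at the
  1st/99th percentiles); confounder adjustment happens entirely through the
  weights.
* ``seq_g`` — sequential g-estimation: an OLS Q-model of Y on X, M and
  confounders gives the mediator coefficient beta_M; the residualized
  outcome Y - beta_M * M is then regressed on X alone to give the CDE.
* ``dr_seq_g`` — doubly robust sequential g-estimation: the Q-model is
  fitted by weighted least squares with the mediator-propensity weights,
  then the residualized-outcome step proceeds as in ``seq_g`` (unweighted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import ols, wls
from .weights import PropensitySpec, compute_mediator_weights, truncate_weights

__all__ = [
    "METHODS",
    "EstimationSpec",
    "EffectEstimates",
    "estimate_total_effect",
    "regression_adjusted_direct",
    "ipw_direct",
    "sequential_g_direct",
    "doubly_robust_direct",
    "indirect_effect",
    "estimate_all_methods",
    "two_confounder_battery",
    "one_confounder_battery",
    "estimates_frame",
]

METHODS = ("regression", "ipw", "ipw_truncated", "seq_g", "dr_seq_g")


@dataclass(frozen=True)
class EstimationSpec:
    """One estimator plus its confounder-inclusion choices.

    ``outcome_confounders`` enter the outcome/Q model (regression, seq_g,
    dr_seq_g); ``propensity_confounders`` enter the mediator propensity
    model (ipw, ipw_truncated, dr_seq_g).  ``label`` distinguishes variants
    of the same method (e.g. the three one-confounder DR variants).
    """

    method: str
    outcome_confounders: tuple[str, ...] = field(default_factory=tuple)
    propensity_confounders: tuple[str, ...] = field(default_factory=tuple)
    label: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.label:
            object.__setattr__(self, "label", self.method)


@dataclass(frozen=True)
class EffectEstimates:
    """One method's effect estimates on one dataset."""

    method: str
    label: str
    total_hat: float
    direct_hat: float
    indirect_hat: float
    b_hat: float = float("nan")
    a_hat: float = float("nan")


def _columns(data: pd.DataFrame, names) -> list[np.ndarray]:
    missing = [c for c in names if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in dataset: {missing}")
    return [data[c].to_numpy(dtype=float) for c in names]


def _check_two_arms(x: np.ndarray) -> None:
    if np.all(x == x[0]):
        raise ValueError("dataset contains a single treatment arm")


def estimate_total_effect(data: pd.DataFrame) -> float:
    """Unadjusted least-squares slope of Y on X (the total effect c)."""
    x = data["X"].to_numpy(dtype=float)
    _check_two_arms(x)
    y = data["Y"].to_numpy(dtype=float)
    coefs, _ = ols(y, [x])
    return float(coefs[1])


def _a_hat(data: pd.DataFrame) -> float:
    """Slope of M on X (diagnostic; the X->M path a)."""
    coefs, _ = ols(data["M"].to_numpy(dtype=float),
                   [data["X"].to_numpy(dtype=float)])
    return float(coefs[1])


def indirect_effect(total_hat: float, direct_hat: float) -> float:
    """Difference-in-coefficients indirect effect, total minus direct."""
    if not (np.isfinite(total_hat) and np.isfinite(direct_hat)):
        raise ValueError("total_hat and direct_hat must be finite")
    return float(total_hat) - float(direct_hat)


def regression_adjusted_direct(data: pd.DataFrame, spec: EstimationSpec,
                               total_hat: float | None = None) -> EffectEstimates:
    """OLS of Y on X, M and the spec's outcome confounders."""
    if total_hat is None:
        total_hat = estimate_total_effect(data)
    y = data["Y"].to_numpy(dtype=float)
    cols = _columns(data, ["X", "M", *spec.outcome_confounders])
    coefs, _ = ols(y, cols)
    direct = float(coefs[1])
    return EffectEstimates(
        method="regression", label=spec.label, total_hat=total_hat,
        direct_hat=direct, indirect_hat=indirect_effect(total_hat, direct),
        b_hat=float(coefs[2]), a_hat=_a_hat(data),
    )


def ipw_direct(data: pd.DataFrame, spec: EstimationSpec, truncate: bool = False,
               total_hat: float | None = None,
               truncation_pcts: tuple[float, float] = (1.0, 99.0)) -> EffectEstimates:
    """Weighted outcome model Y ~ X + M with mediator-propensity weights."""
    if total_hat is None:
        total_hat = estimate_total_effect(data)
    w = compute_mediator_weights(
        data, PropensitySpec(denominator_covariates=tuple(spec.propensity_confounders)))
    if truncate:
        w = truncate_weights(w, *truncation_pcts)
    y = data["Y"].to_numpy(dtype=float)
    cols = _columns(data, ["X", "M"])
    _check_two_arms(cols[0])
    coefs = wls(y, cols, w)
    direct = float(coefs[1])
    return EffectEstimates(
        method="ipw_truncated" if truncate else "ipw", label=spec.label,
        total_hat=total_hat, direct_hat=direct,
        indirect_hat=indirect_effect(total_hat, direct),
        b_hat=float(coefs[2]), a_hat=_a_hat(data),
    )


def sequential_g_direct(data: pd.DataFrame, spec: EstimationSpec,
                        total_hat: float | None = None,
                        weights: np.ndarray | None = None,
                        method: str = "seq_g") -> EffectEstimates:
    """Two-step sequential g-estimation of the CDE.

    Step 1 fits the Q-model Y ~ X + M + confounders (by WLS when ``weights``
    is given, which is the doubly robust variant) and takes the mediator
    coefficient beta_M.  Step 2 regresses the residualized outcome
    Y - beta_M * M on X alone; its slope psi is the CDE.  Because treatment
    is randomized, no baseline covariates enter step 2.
    """
    if total_hat is None:
        total_hat = estimate_total_effect(data)
    y = data["Y"].to_numpy(dtype=float)
    cols = _columns(data, ["X", "M", *spec.outcome_confounders])
    _check_two_arms(cols[0])
    if weights is None:
        coefs, _ = ols(y, cols)
    else:
        coefs = wls(y, cols, weights)
    b_hat = float(coefs[2])
    y_resid = y - b_hat * data["M"].to_numpy(dtype=float)
    step2, _ = ols(y_resid, [cols[0]])
    psi = float(step2[1])
    return EffectEstimates(
        method=method, label=spec.label, total_hat=total_hat,
        direct_hat=psi, indirect_hat=indirect_effect(total_hat, psi),
        b_hat=b_hat, a_hat=_a_hat(data),
    )


def doubly_robust_direct(data: pd.DataFrame, spec: EstimationSpec,
                         total_hat: float | None = None) -> EffectEstimates:
    """Sequential g-estimation with a propensity-weighted Q-model.

    The mediator weights come from ``spec.propensity_confounders``
    (untruncated); the final residual-outcome regression is unweighted.
    The estimate is robust to misspecification of either the propensity
    model or the Q-model, but not both.
    """
    w = compute_mediator_weights(
        data, PropensitySpec(denominator_covariates=tuple(spec.propensity_confounders)))
    return sequential_g_direct(data, spec, total_hat=total_hat, weights=w,
                               method="dr_seq_g")


_DISPATCH = {
    "regression": lambda d, s, t: regression_adjusted_direct(d, s, total_hat=t),
    "ipw": lambda d, s, t: ipw_direct(d, s, truncate=False, total_hat=t),
    "ipw_truncated": lambda d, s, t: ipw_direct(d, s, truncate=True, total_hat=t),
    "seq_g": lambda d, s, t: sequential_g_direct(d, s, total_hat=t),
    "dr_seq_g": lambda d, s, t: doubly_robust_direct(d, s, total_hat=t),
}


def estimate_all_methods(data: pd.DataFrame,
                         estimation_models: list[EstimationSpec]) -> list[EffectEstimates]:
    """Run a battery of estimation specs, sharing one total-effect estimate."""
    if not estimation_models:
        raise ValueError("estimation battery is empty")
    total_hat = estimate_total_effect(data)
    return [_DISPATCH[s.method](data, s, total_hat) for s in estimation_models]


def two_confounder_battery(confounders=("C1", "C2")) -> list[EstimationSpec]:
    """The five correctly specified models: both confounders everywhere."""
    cc = tuple(confounders)
    return [
        EstimationSpec("regression", outcome_confounders=cc),
        EstimationSpec("ipw", propensity_confounders=cc),
        EstimationSpec("ipw_truncated", propensity_confounders=cc),
        EstimationSpec("seq_g", outcome_confounders=cc),
        EstimationSpec("dr_seq_g", outcome_confounders=cc,
                       propensity_confounders=cc),
    ]


def one_confounder_battery(kept: str = "C1",
                           omitted: str = "C2") -> list[EstimationSpec]:
    """The seven misspecified models that omit one confounder.

    Regression, IPW, truncated IPW and sequential g each keep only ``kept``;
    the doubly robust method appears in three variants, omitting ``omitted``
    from the propensity model only, the outcome model only, or both.
    """
    one = (kept,)
    both = (kept, omitted)
    return [
        EstimationSpec("regression", outcome_confounders=one),
        EstimationSpec("ipw", propensity_confounders=one),
        EstimationSpec("ipw_truncated", propensity_confounders=one),
        EstimationSpec("seq_g", outcome_confounders=one),
        EstimationSpec("dr_seq_g", outcome_confounders=both,
                       propensity_confounders=one, label="dr_seq_g_misspec_mediator"),
        EstimationSpec("dr_seq_g", outcome_confounders=one,
                       propensity_confounders=both, label="dr_seq_g_misspec_outcome"),
        EstimationSpec("dr_seq_g", outcome_confounders=one,
                       propensity_confounders=one, label="dr_seq_g_misspec_both"),
    ]


def estimates_frame(estimates: list[EffectEstimates]) -> pd.DataFrame:
    """Estimates as a table: method,spec_label,total_hat,direct_hat,indirect_hat,b_hat,a_hat."""
    return pd.DataFrame([{
        "method": e.method, "spec_label": e.label,
        "total_hat": e.total_hat, "direct_hat": e.direct_hat,
        "indirect_hat": e.indirect_hat, "b_hat": e.b_hat, "a_hat": e.a_hat,
    } for e in estimates])
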