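"""Percentile bootstrap confidence intervals for the indirect effect.

Whole records are resampled with replacement and the complete estimation
pipeline — propensity models, truncation caps, Q-model and total-effect
regressions — is refitted on every resample, so the interval reflects the
uncertainty of all nuisance fits, which is the reason the analytic standard
error of the sequential g-estimator is not trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimationSpec, _DISPATCH, estimate_total_effect

__all__ = ["BootstrapResult", "percentile_bootstrap"]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    lower: float
    upper: float
    n_resamples: int
    level: float

    @property
    def significant(self) -> bool:
        """True when the interval excludes zero."""
        return not (self.lower <= 0.0 <= self.upper)


def _percentile_endpoints(values: np.ndarray, level: float) -> tuple[float, float]:
    # Symmetric nearest-rank rule: with B=1000 and level 0.95 the endpoints
    # are the 25th- and 976th-smallest resampled estimates.
    v = np.sort(values)
    B = len(v)
    k = max(1, math.ceil((1.0 - level) / 2.0 * B - 1e-9))
    return float(v[k - 1]), float(v[B - k])


def percentile_bootstrap(data: pd.DataFrame, spec: EstimationSpec,
                         n_resamples: int = 1000, level: float = 0.95,
                         seed=0) -> BootstrapResult:
    """Percentile bootstrap CI for one estimation spec's indirect effect.

    Resamples with a single treatment arm are redrawn (up to 100 times)
    because no estimator is defined on them.  The same (dataset, spec,
    seed) triple always returns the identical interval.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    x = data["X"].to_numpy()
    if np.all(x == x[0]):
        raise ValueError("dataset contains a single treatment arm")
    estimator = _DISPATCH[spec.method]
    point = estimator(data, spec, estimate_total_effect(data)).indirect_hat
    rng = np.random.default_rng(seed)
    n = len(data)
    draws = np.empty(n_resamples)
    for i in range(n_resamples):
        for attempt in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            if not np.all(x[idx] == x[idx[0]]):
                break
        else:
            raise RuntimeError(
                f"resample {i}: single treatment arm after {_MAX_REDRAWS} redraws"
            )
        boot = data.iloc[idx].reset_index(drop=True)
        draws[i] = estimator(boot, spec, estimate_total_effect(boot)).indirect_hat
    lower, upper = _percentile_endpoints(draws, level)
    return BootstrapResult(point_estimate=float(point), lower=lower, upper=upper,
                           n_resamples=n_resamples, level=level)
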