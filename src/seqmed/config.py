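"""Study configuration files and the packaged illustrative demo scenario."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from . import datagen
from .datagen import PathCoefficients, SimulationCondition, ConditionGrid
from .estimators import (estimate_all_methods, one_confounder_battery,
                         two_confounder_battery)
from .inference import percentile_bootstrap
from .simstudy import StudyConfig

__all__ = ["load_config", "run_demo_scenario", "DEMO_COEFFICIENTS"]

# Demo coefficients: all structural paths large (0.59) with no direct
# effect, giving true indirect effect b*(a + d*g + f*h) = 0.759.
DEMO_COEFFICIENTS = PathCoefficients(a=0.59, b=0.59, c_prime=0.0,
                                     d=0.59, f=0.59, g=0.59, h=0.59)

_KNOWN_KEYS = {
    "replications", "sample_size", "master_seed", "bootstrap",
    "n_resamples", "level", "grid",
}
_GRID_KEYS = {"a_levels", "b_levels", "cprime_levels", "dm_levels",
              "gx_levels"}


def load_config(path) -> StudyConfig:
    """Read a YAML study configuration, filling defaults for missing keys.

    Defaults are the study's reference settings: 1000 replications per
    condition, sample size 500, bootstrap with 1000 resamples at the 95%
    level, and the full factorial condition grid.  Unknown keys raise a
    validation error naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    grid_spec = raw.get("grid") or {}
    if not isinstance(grid_spec, dict):
        raise ValueError("config key 'grid' must be a mapping")
    unknown = set(grid_spec) - _GRID_KEYS
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")
    sample_size = int(raw.get("sample_size", datagen.DEFAULT_SAMPLE_SIZE))
    if sample_size < 4:
        raise ValueError(f"config key 'sample_size' must be >= 4, got {sample_size}")
    replications = int(raw.get("replications", 1000))
    if replications < 1:
        raise ValueError(f"config key 'replications' must be >= 1, got {replications}")
    level = float(raw.get("level", 0.95))
    if not (0.0 < level < 1.0):
        raise ValueError(f"config key 'level' must be in (0, 1), got {level}")
    n_resamples = int(raw.get("n_resamples", 1000))
    if n_resamples < 2:
        raise ValueError(f"config key 'n_resamples' must be >= 2, got {n_resamples}")
    grid = datagen.build_condition_grid(
        a_levels=tuple(grid_spec.get("a_levels", datagen.DEFAULT_A_LEVELS)),
        b_levels=tuple(grid_spec.get("b_levels", datagen.DEFAULT_B_LEVELS)),
        cprime_levels=tuple(grid_spec.get("cprime_levels",
                                          datagen.DEFAULT_CPRIME_LEVELS)),
        dm_levels=tuple(grid_spec.get("dm_levels", datagen.DEFAULT_DM_LEVELS)),
        gx_levels=tuple(grid_spec.get("gx_levels", datagen.DEFAULT_GX_LEVELS)),
        sample_size=sample_size,
    )
    return StudyConfig(
        grid=grid,
        replications=replications,
        master_seed=int(raw.get("master_seed", 0)),
        bootstrap=bool(raw.get("bootstrap", False)),
        n_resamples=n_resamples,
        level=level,
        sample_size=sample_size,
    )


def run_demo_scenario(seed: int = 0, n_resamples: int = 1000,
                      coefficients: PathCoefficients = DEMO_COEFFICIENTS,
                      sample_size: int = 500) -> pd.DataFrame:
    """Illustrative example: one n=500 dataset, all batteries, bootstrap CIs.

    Generates a single dataset under the demo coefficients, runs the five
    correctly specified and seven misspecified estimation models, and
    returns a table with columns battery, method, spec_label, true_value,
    estimate, ci_lower, ci_upper, significant.
    """
    truth = datagen.true_effects(coefficients).indirect
    cond = SimulationCondition(id="demo", coefficients=coefficients,
                               sample_size=sample_size)
    data = datagen.generate_dataset(cond, seed)
    rows = []
    for bat_idx, (bat, specs) in enumerate(
            (("two_confounder", two_confounder_battery()),
             ("one_confounder", one_confounder_battery()))):
        ests = estimate_all_methods(data, specs)
        for spec_idx, (s, e) in enumerate(zip(specs, ests)):
            ci = percentile_bootstrap(
                data, s, n_resamples=n_resamples,
                seed=np.random.SeedSequence([int(seed), bat_idx, spec_idx]))
            rows.append({
                "battery": bat, "method": e.method, "spec_label": e.label,
                "true_value": truth, "estimate": e.indirect_hat,
                "ci_lower": ci.lower, "ci_upper": ci.upper,
                "significant": ci.significant,
            })
    return pd.DataFrame(rows)
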