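"""Synthetic data generation for the single-mediator confounding model.

The structural model has a randomized binary treatment X, two measured
confounders C1 and C2 that are affected both by treatment and by a latent
standard-normal confounder U, a continuous mediator M, and a continuous
outcome Y that U also influences:

    C1 = g*X + k*U + e3
    C2 = h*X + n*U + e4
    M  = a*X + d*C1 + f*C2 + e1
    Y  = c'*X + b*M + t*U + e2

with U, e1..e4 independent standard normal and P(X = 1) = 0.5.  C1 and C2
are mediator-outcome confounders (through U) and, when g or h is nonzero,
post-treatment confounders.  The latent U is retained in generated datasets
for diagnostics only; estimators never read it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PathCoefficients",
    "SimulationCondition",
    "ConditionGrid",
    "TrueEffects",
    "build_condition_grid",
    "build_sign_condition_grid",
    "generate_dataset",
    "true_effects",
    "replication_seed",
    "DATASET_COLUMNS",
    "DEFAULT_A_LEVELS",
    "DEFAULT_B_LEVELS",
    "DEFAULT_CPRIME_LEVELS",
    "DEFAULT_DM_LEVELS",
    "DEFAULT_GX_LEVELS",
    "DEFAULT_SAMPLE_SIZE",
]

DATASET_COLUMNS = ["X", "C1", "C2", "U", "M", "Y"]

# Factor levels of the factorial simulation design (small/medium/large
# unstandardized effects in the Cohen tradition).
DEFAULT_A_LEVELS = (0.14, 0.39, 0.59)
DEFAULT_B_LEVELS = (0.0, 0.14, 0.59)
DEFAULT_CPRIME_LEVELS = (0.0, 0.14, 0.59)
DEFAULT_DM_LEVELS = (0.14, 0.39, 0.59)
DEFAULT_GX_LEVELS = (0.0, 0.14, 0.59)
DEFAULT_SAMPLE_SIZE = 500


@dataclass(frozen=True)
class PathCoefficients:
    """Structural path coefficients of the generating model.

    a: X->M, b: M->Y, c_prime: X->Y direct, d: C1->M, f: C2->M,
    g: X->C1, h: X->C2, k: U->C1, n_coef: U->C2, t: U->Y.
    The latent-confounder paths default to 1.0.
    """

    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    d: float = 0.0
    f: float = 0.0
    g: float = 0.0
    h: float = 0.0
    k: float = 1.0
    n_coef: float = 1.0
    t: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.a, self.b, self.c_prime, self.d, self.f,
                self.g, self.h, self.k, self.n_coef, self.t]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all path coefficients must be finite")


@dataclass(frozen=True)
class SimulationCondition:
    id: str
    coefficients: PathCoefficients
    sample_size: int = DEFAULT_SAMPLE_SIZE

    def __post_init__(self) -> None:
        if self.sample_size < 4:
            raise ValueError(f"sample_size must be >= 4, got {self.sample_size}")


@dataclass(frozen=True)
class ConditionGrid:
    """Ordered, uniquely-keyed list of simulation conditions."""

    conditions: tuple[SimulationCondition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique within a grid")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, i):
        return self.conditions[i]

    def to_frame(self) -> pd.DataFrame:
        """Grid as a table with header id,a,b,c_prime,d,f,g,h,k,n,t,sample_size."""
        rows = []
        for c in self.conditions:
            p = c.coefficients
            rows.append({
                "id": c.id, "a": p.a, "b": p.b, "c_prime": p.c_prime,
                "d": p.d, "f": p.f, "g": p.g, "h": p.h,
                "k": p.k, "n": p.n_coef, "t": p.t,
                "sample_size": c.sample_size,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrueEffects:
    """Population total, controlled direct, and indirect effect."""

    total: float
    cde: float
    indirect: float


def build_condition_grid(
    a_levels=DEFAULT_A_LEVELS,
    b_levels=DEFAULT_B_LEVELS,
    cprime_levels=DEFAULT_CPRIME_LEVELS,
    dm_levels=DEFAULT_DM_LEVELS,
    gx_levels=DEFAULT_GX_LEVELS,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
) -> ConditionGrid:
    """Full factorial grid over (a, b, c', d=f, g=h).

    ``dm_levels`` sets the two confounder-to-mediator paths jointly (d = f)
    and ``gx_levels`` sets the two treatment-to-confounder paths jointly
    (g = h), as in the factorial design; the latent-confounder paths are
    fixed at 1.0.  The default levels yield the 3^5 = 243 condition grid.
    Ids are a zero-padded index over the lexicographic order of
    (a, b, c', d, g).
    """
    for name, levels in [("a_levels", a_levels), ("b_levels", b_levels),
                         ("cprime_levels", cprime_levels),
                         ("dm_levels", dm_levels), ("gx_levels", gx_levels)]:
        if len(tuple(levels)) == 0:
            raise ValueError(f"{name} must be non-empty")
    combos = sorted(itertools.product(a_levels, b_levels, cprime_levels,
                                      dm_levels, gx_levels))
    width = max(3, len(str(len(combos) - 1)))
    conds = []
    for i, (a, b, cp, dm, gx) in enumerate(combos):
        coefs = PathCoefficients(a=a, b=b, c_prime=cp, d=dm, f=dm, g=gx, h=gx)
        conds.append(SimulationCondition(id=f"cond_{i:0{width}d}",
                                         coefficients=coefs,
                                         sample_size=sample_size))
    return ConditionGrid(tuple(conds))


# (d, f) pairs with at least one negative sign, studied with g = h = d.
_SIGN_DF_PAIRS = (
    (-0.14, 0.14), (0.14, -0.14), (-0.14, -0.14),
    (-0.59, 0.59), (0.59, -0.59), (-0.59, -0.59),
)


def build_sign_condition_grid(sample_size: int = DEFAULT_SAMPLE_SIZE) -> ConditionGrid:
    """The 12 opposite-sign confounder conditions.

    Six (d, f) sign combinations crossed with b in {0, 0.59}, holding
    a = 0.59, c' = 0 and g = h = d.
    """
    conds = []
    i = 0
    for d, f in _SIGN_DF_PAIRS:
        for b in (0.0, 0.59):
            coefs = PathCoefficients(a=0.59, b=b, c_prime=0.0,
                                     d=d, f=f, g=d, h=d)
            conds.append(SimulationCondition(id=f"sign_{i:03d}",
                                             coefficients=coefs,
                                             sample_size=sample_size))
            i += 1
    return ConditionGrid(tuple(conds))


def generate_dataset(condition: SimulationCondition, seed) -> pd.DataFrame:
    """Draw one dataset from the structural model.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  The same
    (condition, seed) pair always yields a byte-identical DataFrame with
    columns X, C1, C2, U, M, Y.
    """
    if condition.sample_size <= 0:
        raise ValueError("sample_size must be positive")
    rng = np.random.default_rng(seed)
    p = condition.coefficients
    n = condition.sample_size
    X = rng.binomial(1, 0.5, size=n).astype(np.int64)
    U = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    e3 = rng.standard_normal(n)
    e4 = rng.standard_normal(n)
    C1 = p.g * X + p.k * U + e3
    C2 = p.h * X + p.n_coef * U + e4
    M = p.a * X + p.d * C1 + p.f * C2 + e1
    Y = p.c_prime * X + p.b * M + p.t * U + e2
    return pd.DataFrame({"X": X, "C1": C1, "C2": C2, "U": U, "M": M, "Y": Y})


def true_effects(coefficients: PathCoefficients) -> TrueEffects:
    """Population effects by path tracing.

    The controlled direct effect is c' (no X-M interaction), and the total
    indirect effect through M sums the paths X->M and X->C1->M, X->C2->M,
    each multiplied by b: indirect = b*(a + d*g + f*h).
    """
    p = coefficients
    total = p.c_prime + p.b * (p.a + p.d * p.g + p.f * p.h)
    # indirect is defined as total minus CDE, exactly, also in floating point
    return TrueEffects(total=total, cde=p.c_prime, indirect=total - p.c_prime)


def replication_seed(master_seed: int, condition_index: int,
                     replication_index: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed.

    Derived from the triple (master seed, condition index, replication
    index), so results do not depend on execution order and replications
    can run in parallel.
    """
    return np.random.SeedSequence([int(master_seed), int(condition_index),
                                   int(replication_index)])


def condition_with_sample_size(condition: SimulationCondition,
                               sample_size: int) -> SimulationCondition:
    """Copy of ``condition`` with a different sample size."""
    return replace(condition, sample_size=sample_size)
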