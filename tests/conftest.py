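import itertools

import numpy as np
import pandas as pd
import pytest

from seqmed import PathCoefficients, SimulationCondition, generate_dataset


@pytest.fixture(scope="session")
def noise_free_dataset() -> pd.DataFrame:
    """Fully balanced deterministic dataset with exact linear structure.

    X in {0,1} crossed with e1 in {-1,1} and C1 in {-1,1};
    M = 0.59*X + 0.3*C1 + e1 and Y = 0.2*X + 0.59*M with no noise, so the
    total effect is exactly 0.2 + 0.59*0.59 = 0.5481 and every coefficient
    is exactly recoverable.
    """
    rows = []
    for x, e1, c1 in itertools.product((0, 1), (-1.0, 1.0), (-1.0, 1.0)):
        m = 0.59 * x + 0.3 * c1 + e1
        y = 0.2 * x + 0.59 * m
        rows.append({"X": x, "C1": c1, "C2": 0.5 * c1 - 0.5, "M": m, "Y": y})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def medium_dataset() -> pd.DataFrame:
    """One n=500 draw from a moderately confounded condition."""
    cond = SimulationCondition(
        "fixture",
        PathCoefficients(a=0.39, b=0.59, c_prime=0.14, d=0.39, f=0.39,
                         g=0.14, h=0.14),
        sample_size=500)
    return generate_dataset(cond, seed=12345)


def random_linear_dataset(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """Arbitrary dataset with both treatment arms, for algebraic identities."""
    X = rng.integers(0, 2, size=n)
    X[0], X[1] = 0, 1  # guarantee two arms
    C1 = rng.standard_normal(n)
    C2 = rng.standard_normal(n)
    M = rng.standard_normal(n) + 0.5 * X
    Y = rng.standard_normal(n) + 0.3 * X + 0.4 * M
    return pd.DataFrame({"X": X, "C1": C1, "C2": C2, "M": M, "Y": Y})
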