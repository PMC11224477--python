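import numpy as np
import pandas as pd
import pytest

from grainfill import LogisticParams


@pytest.fixture
def ref_params() -> LogisticParams:
    """A typical maize filling curve: ~30 g asymptote, peak near day 25."""
    return LogisticParams(A=30.0, B=40.0, C=0.15)


@pytest.fixture
def field_schedule() -> np.ndarray:
    """The standard sampling schedule: 15 d after pollination, every 5 d."""
    return 15.0 + 5.0 * np.arange(9)


def random_valid_params(rng: np.random.Generator, n: int) -> list[LogisticParams]:
    """Parameter triples in the realistic trial regime (lnB safely > 1.317)."""
    A = rng.uniform(25.0, 40.0, n)
    lnB = rng.uniform(2.5, 4.5, n)
    C = rng.uniform(0.10, 0.20, n)
    return [LogisticParams(a, float(np.exp(b)), c) for a, b, c in zip(A, lnB, C)]


def balanced_frame(y: np.ndarray, reps=None, tillage=None, variety=None) -> pd.DataFrame:
    """Long-format trait records from a (replicate, tillage, variety) array."""
    r, m, v = y.shape
    reps = reps or list(range(1, r + 1))
    tillage = tillage or [f"T{j}" for j in range(m)]
    variety = variety or [f"V{k}" for k in range(v)]
    rows = [
        {"year": 2020, "tillage": tillage[j], "variety": variety[k],
         "replicate": reps[i], "value": float(y[i, j, k])}
        for i in range(r) for j in range(m) for k in range(v)
    ]
    return pd.DataFrame(rows)
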