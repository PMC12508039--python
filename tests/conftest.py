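"""Shared fixtures: small simulated cohorts and hand-built toy tables."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hdss.simulate import generate_cohort, preset


def make_tiny_cohort() -> pd.DataFrame:
    """Four persons x 2 timepoints x 4 items, hand-enumerable."""
    rows = []
    items = {
        ("a", 1): [0, 1, 2, 0],
        ("a", 2): [1, 1, 2, 0],
        ("b", 1): [2, 2, 0, 1],
        ("b", 2): [2, 2, 0, 1],
        ("c", 1): [0, 0, 0, 0],
        ("c", 2): [0, 1, 0, 0],
        ("d", 1): [1, 0, 1, 2],
        ("d", 2): [2, 0, 1, 2],
    }
    demo = {"a": ("A", "female", 9.0), "b": ("B", "male", 10.0),
            "c": ("A", "male", 9.5), "d": ("B", "female", 10.5)}
    for (pid, tp), vals in items.items():
        race, gender, age = demo[pid]
        row = {"person_id": pid, "timepoint": tp,
               "race": race, "gender": gender, "age": age + (tp - 1)}
        for j, v in enumerate(vals, start=1):
            row[f"item_{j:03d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_cohort() -> pd.DataFrame:
    return make_tiny_cohort()


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally full simulated cohort with its truth."""
    cfg = replace(preset("paper_like", seed=11), n_persons=80)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_sim():
    """Medium cohort for statistical checks (shared across tests)."""
    cfg = replace(preset("paper_like", seed=5), n_persons=400)
    return generate_cohort(cfg)


def pairwise_oracle(X: np.ndarray) -> np.ndarray:
    """Naive double-loop Euclidean distance matrix (independent oracle)."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(X.shape[1]):
                s += (X[i, k] - X[j, k]) ** 2
            D[i, j] = s ** 0.5
    return D
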