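"""Shared fixtures: the T1 toy decision table and brute-force rough-set oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from opca.rough_set import DecisionTable

# Four normalized samples over two genes, two per class; gene a1 separates the
# classes at radius 0.2 but mixes everything at radius 1.0.
T1_ATTRIBUTES = np.array(
    [
        [0.0, 0.0],
        [0.1, 0.0],
        [0.9, 1.0],
        [1.0, 0.9],
    ]
)
T1_DECISION = np.array(["+", "+", "-", "-"], dtype=object)


@pytest.fixture
def t1_table():
    """Factory: the T1 table at a chosen radius."""

    def make(delta: float) -> DecisionTable:
        return DecisionTable(T1_ATTRIBUTES.copy(), T1_DECISION.copy(), delta)

    return make


# ---------------------------------------------------------------------------
# Brute-force oracles: independent double-loop enumeration, no vectorization.


def brute_neighborhood(i, B, table):
    B = sorted(set(B))
    out = set()
    for j in range(table.n_samples):
        if not B:
            out.add(j)
            continue
        d = sum((table.attributes[i, b] - table.attributes[j, b]) ** 2 for b in B) ** 0.5
        if d <= table.delta:
            out.add(j)
    return out


def brute_lower_approximation(c, B, table):
    members = {j for j in range(table.n_samples) if table.decision[j] == c}
    return {
        i
        for i in range(table.n_samples)
        if brute_neighborhood(i, B, table) <= members
    }


def brute_positive_region(B, table):
    out = set()
    for c in set(table.decision.tolist()):
        out |= brute_lower_approximation(c, B, table)
    return out


def brute_dependency(B, table):
    return len(brute_positive_region(B, table)) / table.n_samples


@pytest.fixture
def oracles():
    return SimpleNamespace(
        neighborhood=brute_neighborhood,
        lower_approximation=brute_lower_approximation,
        positive_region=brute_positive_region,
        dependency=brute_dependency,
    )


def random_table(rng, n_samples=None, n_genes=None, delta=None) -> DecisionTable:
    """A random normalized two-class decision table (both classes present)."""
    n = int(n_samples if n_samples is not None else rng.integers(4, 21))
    m = int(n_genes if n_genes is not None else rng.integers(1, 6))
    X = rng.uniform(0.0, 1.0, size=(n, m))
    y = np.array(["a"] * n, dtype=object)
    k = int(rng.integers(1, n))
    y[rng.permutation(n)[:k]] = "b"
    d = float(rng.uniform(0.0, 2.0)) if delta is None else float(delta)
    return DecisionTable(X, y, d)


@pytest.fixture
def make_random_table():
    return random_table
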