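"""Neighborhood rough-set engine: toy-table exactness, oracle agreement,
monotonicity and determinism of the greedy reduct."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opca.rough_set import (
    DecisionTable,
    dependency,
    greedy_reduct,
    lower_approximation,
    neighborhood,
    normalize_attributes,
    positive_region,
    radius_search,
    significance,
)
from conftest import random_table


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        out = normalize_attributes(np.array([[0.0], [5.0], [10.0]]))
        assert np.allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = normalize_attributes(np.array([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]]))
        assert np.all(out[:, 0] == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        once = normalize_attributes(X)
        assert np.allclose(normalize_attributes(once), once)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            normalize_attributes(np.array([[0.0], [np.nan]]))


class TestToyTable:
    """All values on T1 enumerable by hand."""

    def test_neighborhoods_small_radius(self, t1_table):
        t = t1_table(0.2)
        assert set(neighborhood(0, [0], t)) == {0, 1}
        assert set(neighborhood(2, [0], t)) == {2, 3}

    def test_neighborhood_large_radius_is_universe(self, t1_table):
        t = t1_table(1.0)
        assert set(neighborhood(0, [0], t)) == {0, 1, 2, 3}

    def test_empty_subset_neighborhood_is_universe(self, t1_table):
        t = t1_table(0.2)
        assert set(neighborhood(0, [], t)) == {0, 1, 2, 3}

    def test_lower_approximation(self, t1_table):
        assert set(lower_approximation("+", [0], t1_table(0.2))) == {0, 1}
        assert set(lower_approximation("+", [0], t1_table(1.0))) == set()

    def test_positive_region(self, t1_table):
        assert set(positive_region([0], t1_table(0.2))) == {0, 1, 2, 3}
        assert set(positive_region([0], t1_table(1.0))) == set()

    def test_dependency(self, t1_table):
        assert dependency([0], t1_table(0.2)) == 1.0
        assert dependency([0], t1_table(1.0)) == 0.0
        assert dependency([], t1_table(0.2)) == 0.0

    def test_significance_of_first_gene(self, t1_table):
        assert significance(0, [], t1_table(0.2)) == 1.0
        assert significance(0, [0], t1_table(0.2)) == 0.0

    def test_greedy_reduct_picks_first_of_tied_genes(self, t1_table):
        r = greedy_reduct(t1_table(0.2), 0.01)
        assert r.selected == (0,)
        assert r.final_dependency == 1.0
        assert r.significance_trace == (1.0,)

    def test_unknown_class_and_bad_index_raise(self, t1_table):
        with pytest.raises(ValueError, match="unknown class"):
            lower_approximation("?", [0], t1_table(0.2))
        with pytest.raises(IndexError):
            neighborhood(9, [0], t1_table(0.2))


class TestOracleAgreement:
    def test_all_operations_match_enumeration(self, oracles):
        rng = np.random.default_rng(42)
        for _ in range(30):
            t = random_table(rng)
            B = [int(b) for b in rng.permutation(t.n_genes)[: rng.integers(0, t.n_genes + 1)]]
            i = int(rng.integers(t.n_samples))
            assert set(neighborhood(i, B, t)) == oracles.neighborhood(i, B, t)
            for c in t.classes:
                assert set(lower_approximation(c, B, t)) == oracles.lower_approximation(c, B, t)
            assert set(positive_region(B, t)) == oracles.positive_region(B, t)
            assert dependency(B, t) == oracles.dependency(B, t)


class TestMonotonicity:
    def test_neighborhood_symmetry_and_reflexivity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = random_table(rng)
            B = list(range(t.n_genes))
            for i in range(t.n_samples):
                ni = set(neighborhood(i, B, t))
                assert i in ni
                for j in ni:
                    assert i in set(neighborhood(int(j), B, t))

    def test_dependency_monotone_in_attributes(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            t = random_table(rng, n_genes=4)
            small = [int(b) for b in rng.permutation(4)[:2]]
            big = sorted(set(small) | {int(rng.integers(4))})
            assert dependency(small, t) <= dependency(big, t) + 1e-12

    def test_dependency_antimonotone_in_radius(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            t = random_table(rng)
            B = list(range(t.n_genes))
            d1, d2 = sorted(rng.uniform(0, 2, size=2))
            t1 = DecisionTable(t.attributes, t.decision, d1)
            t2 = DecisionTable(t.attributes, t.decision, d2)
            assert dependency(B, t1) >= dependency(B, t2) - 1e-12

    def test_significance_nonnegative_even_for_duplicate_columns(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(size=4)
        X = normalize_attributes(np.column_stack([x, x]))
        t = DecisionTable(X, np.array(["a", "a", "b", "b"], dtype=object), 0.5)
        assert significance(1, [0], t) >= 0.0
        for _ in range(30):
            t = random_table(rng)
            a = int(rng.integers(t.n_genes))
            B = [int(b) for b in rng.permutation(t.n_genes)[: rng.integers(0, t.n_genes)]]
            assert significance(a, B, t) >= 0.0


class TestGreedyReduct:
    def test_floor_of_one_blocks_everything(self, t1_table):
        r = greedy_reduct(t1_table(0.2), 1.0)
        assert r.selected == ()
        assert r.final_dependency == 0.0

    def test_deterministic_and_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            t = random_table(rng, n_samples=12, n_genes=5)
            r1 = greedy_reduct(t, 0.01)
            r2 = greedy_reduct(t, 0.01)
            assert r1 == r2
            assert len(r1.selected) <= t.n_genes
            assert all(
                b >= a for a, b in zip(r1.dependency_trace, r1.dependency_trace[1:])
            )

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(29)
        for _ in range(8):
            t = random_table(rng, n_samples=12, n_genes=6, delta=float(rng.uniform(0, 0.8)))
            best = max(
                dependency(list(S), t)
                for k in range(7)
                for S in itertools.combinations(range(6), k)
            )
            assert greedy_reduct(t, 0.01).final_dependency <= best + 1e-12

    def test_forward_search_can_stall_at_a_local_optimum(self):
        """Forward selection is a heuristic: there exist tables where no single
        gene improves the current subset yet a larger subset reaches full
        dependency.  This pins one such table as a regression case."""
        rng = np.random.default_rng(29)
        found = False
        for _ in range(8):
            t = random_table(rng, n_samples=12, n_genes=6, delta=float(rng.uniform(0, 0.8)))
            best = max(
                dependency(list(S), t)
                for k in range(7)
                for S in itertools.combinations(range(6), k)
            )
            r = greedy_reduct(t, 0.01)
            if best == 1.0 and r.final_dependency < 1.0:
                found = True
                # stalling means every remaining gene adds zero dependency
                for a in set(range(6)) - set(r.selected):
                    assert significance(a, r.selected, t) == 0.0
        assert found


class TestRadiusSearch:
    def test_dependency_scoring_prefers_separating_radius(self, t1_table):
        X, y = t1_table(0.2).attributes, t1_table(0.2).decision
        delta, reduct = radius_search(X, y, [0.2, 1.0], 0.01)
        assert delta == 0.2
        assert reduct.final_dependency == 1.0

    def test_singleton_grid_returns_it(self, t1_table):
        t = t1_table(0.2)
        delta, _ = radius_search(t.attributes, t.decision, [0.7], 0.01)
        assert delta == 0.7

    def test_duplicate_grid_entries_equal_deduplicated(self, t1_table):
        t = t1_table(0.2)
        a = radius_search(t.attributes, t.decision, [0.2, 0.2, 1.0, 1.0], 0.01)
        b = radius_search(t.attributes, t.decision, [0.2, 1.0], 0.01)
        assert a == b

    def test_empty_grid_raises(self, t1_table):
        t = t1_table(0.2)
        with pytest.raises(ValueError, match="non-empty"):
            radius_search(t.attributes, t.decision, [], 0.01)


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
def test_normalization_bounds_hold_for_any_column(values):
    out = normalize_attributes(np.asarray(values)[:, None])
    assert out.min() >= 0.0 and out.max() <= 1.0
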