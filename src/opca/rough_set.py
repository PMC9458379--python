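"""Neighborhood rough-set engine for two-class decision tables.

Samples are granulated by closed Euclidean balls of radius ``delta`` measured
on a gene subset B of min-max normalized attributes.  A sample belongs to the
positive region of B when its whole neighborhood shares its decision class;
the dependency degree gamma_B = |POS_B| / |U| measures how consistently B
classifies the universe.  Attribute significance is the dependency gain from
adding one gene, and the reduct search greedily accepts the most significant
gene while the gain clears a floor.

Distances are raw Euclidean over B (no division by sqrt(|B|)), so adding a
gene can only grow distances, shrink neighborhoods and raise dependency —
the monotonicity the greedy search relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DecisionTable",
    "ReductResult",
    "normalize_attributes",
    "neighborhood",
    "lower_approximation",
    "positive_region",
    "dependency",
    "significance",
    "greedy_reduct",
    "radius_search",
]


def normalize_attributes(matrix: np.ndarray) -> np.ndarray:
    """Min-max normalize each gene column to [0, 1]; constant genes map to 0.

    Normalization makes a radius in [0, 2] commensurate across genes and is
    idempotent: values already in [0, 1] with full range are unchanged.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("attributes contain non-finite values")
    if X.shape[0] < 2:
        raise ValueError("normalization requires at least two samples")
    lo = X.min(axis=0, keepdims=True)
    span = X.max(axis=0, keepdims=True) - lo
    span = np.where(span == 0, 1.0, span)
    return (X - lo) / span


@dataclass(frozen=True)
class DecisionTable:
    """Normalized attributes, a two-class decision column and a radius.

    ``attributes`` is samples x genes with every value in [0, 1]; ``decision``
    holds one of exactly two class symbols per sample; ``delta`` is the
    neighborhood radius in [0, 2].
    """

    attributes: np.ndarray
    decision: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        X = np.asarray(self.attributes, dtype=float)
        y = np.asarray(self.decision, dtype=object)
        object.__setattr__(self, "attributes", X)
        object.__setattr__(self, "decision", y)
        if X.ndim != 2:
            raise ValueError("attributes must be 2-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError("attribute rows and decision length differ")
        if X.size and ((X < 0).any() or (X > 1).any()):
            raise ValueError("attributes must be min-max normalized to [0, 1]")
        if len(set(y.tolist())) != 2:
            raise ValueError("decision must contain exactly two classes")
        if not 0.0 <= self.delta <= 2.0:
            raise ValueError("delta must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.attributes.shape[0]

    @property
    def n_genes(self) -> int:
        return self.attributes.shape[1]

    @property
    def classes(self) -> tuple:
        return tuple(sorted(set(self.decision.tolist())))


@dataclass(frozen=True)
class ReductResult:
    """Outcome of a greedy reduct search.

    ``selected`` is the ordered list of accepted gene indices;
    ``significance_trace[r]`` is the dependency gain the r-th gene delivered
    when accepted; ``dependency_trace[r]`` is the dependency after accepting
    it (non-decreasing); ``final_dependency`` equals the last trace entry or
    0 for an empty reduct.
    """

    selected: tuple[int, ...]
    significance_trace: tuple[float, ...]
    dependency_trace: tuple[float, ...]
    delta_used: float
    final_dependency: float

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be distinct")
        if len(self.selected) != len(self.significance_trace) or len(
            self.selected
        ) != len(self.dependency_trace):
            raise ValueError("traces must match the selection length")
        if any(
            b < a - 1e-12
            for a, b in zip(self.dependency_trace, self.dependency_trace[1:])
        ):
            raise ValueError("dependency trace must be non-decreasing")
        expect = self.dependency_trace[-1] if self.dependency_trace else 0.0
        if abs(self.final_dependency - expect) > 1e-12:
            raise ValueError("final_dependency must equal the last trace entry")


def _subset(B: Iterable[int], n_genes: int) -> np.ndarray:
    idx = np.asarray(sorted(set(int(b) for b in B)), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_genes):
        raise IndexError(f"gene subset {idx.tolist()} out of range for {n_genes} genes")
    return idx


def neighborhood(i: int, B: Iterable[int], table: DecisionTable) -> np.ndarray:
    """Indices of samples within delta of sample i on subset B (closed ball).

    Always contains i itself; with B empty all distances are 0, so the
    neighborhood is the whole universe.
    """
    n = table.n_samples
    if not 0 <= i < n:
        raise IndexError(f"sample index {i} out of range for {n} samples")
    idx = _subset(B, table.n_genes)
    if idx.size == 0:
        return np.arange(n)
    diffs = table.attributes[:, idx] - table.attributes[i, idx]
    d2 = np.einsum("ij,ij->i", diffs, diffs)
    return np.flatnonzero(d2 <= table.delta**2)


def _membership(B: Iterable[int], table: DecisionTable) -> np.ndarray:
    """Boolean n x n matrix: memb[i, j] iff j is in the neighborhood of i."""
    n = table.n_samples
    idx = _subset(B, table.n_genes)
    if idx.size == 0:
        return np.ones((n, n), dtype=bool)
    X = table.attributes[:, idx]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    return d2 <= table.delta**2


def lower_approximation(c, B: Iterable[int], table: DecisionTable) -> np.ndarray:
    """Samples whose whole neighborhood lies inside decision class c."""
    if c not in table.classes:
        raise ValueError(f"unknown class {c!r}; table classes are {table.classes}")
    memb = _membership(B, table)
    in_c = table.decision == c
    pure = ~(memb & ~in_c[None, :]).any(axis=1)
    return np.flatnonzero(pure)


def positive_region(B: Iterable[int], table: DecisionTable) -> np.ndarray:
    """Union of lower approximations over the decision classes."""
    memb = _membership(B, table)
    pos = np.zeros(table.n_samples, dtype=bool)
    for c in table.classes:
        in_c = table.decision == c
        pos |= in_c & ~(memb & ~in_c[None, :]).any(axis=1)
    return np.flatnonzero(pos)


def dependency(B: Iterable[int], table: DecisionTable) -> float:
    """gamma_B = |POS_B| / |U|; 0 for the empty subset on a two-class table."""
    return positive_region(B, table).size / table.n_samples


def significance(a: int, B: Iterable[int], table: DecisionTable) -> float:
    """Dependency gain from adding gene a to subset B; 0 when a already in B.

    Non-negative by attribute monotonicity: extra coordinates can only grow
    Euclidean distances, hence shrink neighborhoods.
    """
    Bset = set(int(b) for b in B)
    a = int(a)
    if a in Bset:
        return 0.0
    return dependency(Bset | {a}, table) - dependency(Bset, table)


def _pairwise_sq_diffs(X: np.ndarray) -> np.ndarray:
    """Stack of per-gene squared pairwise differences, shape (genes, n, n)."""
    Xt = np.ascontiguousarray(X.T)
    return (Xt[:, :, None] - Xt[:, None, :]) ** 2


def _pure_fraction(d2: np.ndarray, delta: float, class_mask: np.ndarray) -> np.ndarray:
    """Dependency for each candidate distance matrix in a (r, n, n) stack."""
    memb = d2 <= delta * delta
    # neighbor counts per class; a sample is in POS iff its neighborhood is pure
    pos_counts = memb @ class_mask.astype(float)  # (r, n) neighbors in class "1"
    tot_counts = memb.sum(axis=-1).astype(float)
    same = np.where(class_mask[None, :], pos_counts, tot_counts - pos_counts)
    pure = same == tot_counts
    return pure.mean(axis=-1)


def greedy_reduct(
    table: DecisionTable,
    significance_floor: float = 0.01,
    *,
    _diff2: np.ndarray | None = None,
) -> ReductResult:
    """Forward selection of genes by maximal significance, gated by a floor.

    Starting from the empty subset, repeatedly add the gene with the largest
    dependency gain (ties broken toward the lower index) while that gain
    exceeds ``significance_floor`` and genes remain.  Fully deterministic.
    """
    if significance_floor < 0:
        raise ValueError("significance_floor must be >= 0")
    X = table.attributes
    n, m = X.shape
    diff2 = _pairwise_sq_diffs(X) if _diff2 is None else _diff2
    class_mask = table.decision == table.classes[1]

    current = np.zeros((n, n))
    remaining = np.arange(m)
    selected: list[int] = []
    sig_trace: list[float] = []
    dep_trace: list[float] = []
    dep = 0.0
    while remaining.size:
        deps = _pure_fraction(current[None, :, :] + diff2[remaining], table.delta, class_mask)
        best = int(np.argmax(deps))  # first max -> lowest gene index
        gain = float(deps[best]) - dep
        if gain <= significance_floor:
            break
        j = int(remaining[best])
        selected.append(j)
        sig_trace.append(gain)
        dep = float(deps[best])
        dep_trace.append(dep)
        current = current + diff2[j]
        remaining = remaining[remaining != j]
    return ReductResult(
        selected=tuple(selected),
        significance_trace=tuple(sig_trace),
        dependency_trace=tuple(dep_trace),
        delta_used=float(table.delta),
        final_dependency=dep_trace[-1] if dep_trace else 0.0,
    )


def radius_search(
    attributes: np.ndarray,
    decision: Sequence,
    delta_grid: Sequence[float],
    significance_floor: float = 0.01,
    evaluator: Callable[[ReductResult], float] | None = None,
) -> tuple[float, ReductResult]:
    """Sweep the radius grid, score each greedy reduct, return the best radius.

    The score is ``evaluator(reduct)`` (typically cross-validated accuracy)
    when an evaluator is supplied, else the reduct's final dependency.  Empty
    reducts score -inf under an evaluator so any non-empty panel beats them.
    Ties go to the reduct with fewer genes, then to the smaller radius.
    """
    grid = np.unique(np.asarray(list(delta_grid), dtype=float))
    if grid.size == 0:
        raise ValueError("delta grid must be non-empty")
    if (grid < 0).any() or (grid > 2).any():
        raise ValueError("all radii must lie in [0, 2]")
    X = np.asarray(attributes, dtype=float)
    y = np.asarray(list(decision), dtype=object)
    diff2 = _pairwise_sq_diffs(X)

    score_cache: dict[tuple[int, ...], float] = {}
    best: tuple[float, int, float, ReductResult] | None = None
    for delta in grid:  # ascending, so ties naturally keep the smaller radius
        table = DecisionTable(X, y, float(delta))
        reduct = greedy_reduct(table, significance_floor, _diff2=diff2)
        key = reduct.selected
        if key not in score_cache:
            if evaluator is None:
                score_cache[key] = reduct.final_dependency
            elif not key:
                score_cache[key] = float("-inf")
            else:
                score_cache[key] = float(evaluator(reduct))
        score = score_cache[key]
        cand = (score, -len(reduct.selected), -delta, reduct)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = (score, -len(reduct.selected), float(delta), reduct)
    return best[2], best[3]
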