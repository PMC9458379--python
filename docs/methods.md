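# Methods

## Model and procedure

The package addresses two-class feature selection on expression matrices
where genes vastly outnumber samples. It combines a variance-share filter
(PCA contribution rates) with a consistency-based wrapper (neighborhood
rough-set attribute reduction), so the expensive combinatorial search only
ever sees genes that carry appreciable variance.

**Covariance and contribution rates.** The gene–gene covariance is the
population form H = (1/M) Σₖ (xₖ − x̄)(xₖ − x̄)ᵀ, divisor M = sample count
(`ddof=0`; the unbiased M−1 form is available via `ddof=1`). Eigenvalues
are clipped at zero below −1e−10, sorted descending, and each eigenvector's
sign is fixed by making its largest-magnitude entry non-negative (ties to
the lower index), so decompositions are bit-reproducible. Contribution
rates cₖ = βₖ/Σβ are defined only when total variance is positive;
all-constant data is rejected as degenerate.

**From components to genes.** A component-level threshold cannot by itself
output genes, yet the downstream reduction needs gene columns. The filter
therefore retains components with cₖ above the threshold (default 1%),
scores gene j as sⱼ = Σₖ cₖ l²ₖⱼ over retained components — gene j's share
of the retained variance — renormalizes the scores to sum 1, and applies
the same 1% rule at gene level. The sⱼ are non-negative and sum to one, so
the gate is scale-free. Should no gene clear the gate (flat spectra), the
top ⌈√m⌉ genes by score are kept so the pipeline never stalls; tie-breaks
go to the lower index. An alternative reading — thresholding per-gene raw
variance share — was considered and rejected because it ignores the
correlation structure the components capture.

**Neighborhood rough set.** Candidate columns are min–max normalized to
[0, 1] (constant columns map to zero), making a single radius δ ∈ [0, 2]
commensurate across genes. Neighborhoods are closed Euclidean balls over
the current subset B, always containing the sample itself; for B = ∅ the
distance is defined as 0, so the neighborhood is the whole universe and the
empty subset has dependency 0 on any two-class table. Distances are raw
Euclidean (not divided by √|B|): this preserves the monotonicity that adding
a gene can only grow distances, shrink neighborhoods and raise dependency,
which both the greedy search's correctness argument and the test suite's
monotonicity properties rely on. Dependency is γ_B = |POS_B|/|U| with the
positive region the union of class-wise lower approximations, and
significance is the dependency gain of a single added gene — hence always
non-negative.

**Greedy reduct and radius sweep.** Forward selection accepts the most
significant gene (ties to the lowest index) while the gain exceeds the
significance floor (default 0.01). The radius is swept over a grid
(default 0.00–2.00, step 0.01); each radius's reduct is scored by
cross-validated accuracy of the selected panel, ties resolved toward fewer
genes and then the smaller radius, and identical reducts arising at
different radii are scored once (cached). Scoring falls back to final
dependency when no evaluator is supplied, and empty reducts score −∞ under
an evaluator so any non-empty panel beats them. With a singleton grid the
sweep degenerates to a fixed radius, reproducing published per-dataset
settings such as δ = 0.77 or 0.19 directly. A "multi-neighborhood" search
is realized as this one-radius-at-a-time sweep; simultaneous multi-radius
granulation is out of scope.

**Evaluation protocol.** Stratified k-fold cross-validation (default
10-fold, seeded shuffle) with a linear SVM (C = 1) or 1-NN; confusion
counts are pooled over folds before computing accuracy and positive-class
precision (precision is 0 when no positive predictions exist). The
positive class defaults to the lexicographically larger label and can be
overridden. By default the gene panel is selected once on the full dataset
and held fixed across folds — the selection therefore leaks into the
estimate, which is visibly optimistic on null data (~0.63 at n = 60 in our
measurements). `nested_cross_validate` (CLI `--nested`) re-runs the entire
selection inside each training fold for an unbiased, typically lower,
estimate. Chance-level calibration checks consequently use a fixed panel
on zero-effect data, where the protocol is unbiased.

## Synthetic data

The generator emulates the shape of two-class tumor microarray studies:
tens of samples, thousands of genes, a handful of class-separated genes.
Informative genes are N(0, 1) in the negative class and N(effect, 1) in the
positive class; redundant genes are cyclic noisy copies of informative
parents (additive N(0, σ_red)); noise genes are N(0, 1) everywhere. Gene
order is shuffled deterministically by the seed and a truth table records
each gene's role and parent. Defaults — 30 + 30 samples, 6 informative at
a 2 SD effect, 20 redundant (σ_red = 0.5), 174 noise — give a 60 × 200
design in which the planted panel is recoverable but far from trivial
(noise genes outnumber signal 6.7 : 1). What the generator does **not**
model: probe- and batch-effects, heavy-tailed intensity distributions,
intensity-dependent variance, correlated noise blocks. Passing tests on
this generator demonstrate that the machinery recovers planted structure
under Gaussian assumptions, not that it will match any particular published
panel on real arrays.

## Numerical choices

- Ball membership is evaluated on squared distances (d² ≤ δ²), exactly
  equivalent to the metric definition and cheaper; no tolerance fudge is
  added.
- All tie-breaks (gene index, radius) are deterministic, and every source
  of randomness (fold shuffling, simulation) flows from an explicit seed,
  so repeated runs are byte-identical.
- The greedy engine updates a running matrix of pairwise squared distances,
  so adding a candidate gene costs O(n²) rather than a fresh O(n²·|B|)
  distance computation.
- Loader policy: missing or non-numeric cells are rejected with their
  coordinates by default; per-gene mean imputation is available behind a
  flag. On-disk matrices default to genes-as-rows, the dominant microarray
  convention.

## Known limitations

- Forward selection is a heuristic: tables exist where no single gene
  improves the current subset yet a larger subset reaches full dependency.
  We measured such stalls in roughly 14% of random 12-sample × 6-gene
  tables whose optimum reaches dependency 1.0; one concrete case is pinned
  as a regression test. The greedy result is always bounded above by the
  exhaustive optimum.
- The default (non-nested) protocol overstates accuracy whenever selection
  has seen the evaluation data; use `--nested` for honest estimates.
- Only two-class decisions are supported; multi-class reduction, fuzzy or
  variable-precision rough sets, and approximate nearest-neighbor
  acceleration are out of scope.
- The radius sweep evaluates a full reduct per grid point; for very large
  candidate sets a coarser grid (e.g. step 0.1) is advisable.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` exercise the pipeline on the
default 60 × 200 design (10–20 independent seeds), ablation comparisons on
a few seeds, and an end-to-end run at the colon-benchmark shape
(62 × 2000, 22/40 split) at a fixed radius — sizes chosen so the whole
battery of properties (exact oracle agreement, monotonicity, recovery,
chance-level nulls, reproducibility) runs comfortably on a single CPU.
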