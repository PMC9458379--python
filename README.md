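# opca — tumor gene panel selection with PCA filtering and neighborhood rough sets

`opca` selects small, discriminative gene panels from two-class expression
matrices (tumor vs. normal microarray or bulk expression studies). It is
aimed at analysts who need a handful of marker genes out of thousands of
probes, together with an honest cross-validated estimate of how well that
panel classifies.

## Method

The selector runs in two stages:

1. **PCA contribution-rate filter.** From the gene–gene covariance
   H = (1/M) Σₖ (xₖ − x̄)(xₖ − x̄)ᵀ the eigenpairs (βₖ, lₖ) are computed and
   each component's contribution rate cₖ = βₖ / Σⱼ βⱼ is taken. Components
   with cₖ > 1% are retained, every gene is scored by its
   contribution-weighted squared loadings sⱼ = Σₖ cₖ l²ₖⱼ (renormalized to
   sum 1), and genes with sⱼ > 1% become the candidate set.

2. **Neighborhood rough-set reduction.** Candidate columns are min–max
   normalized and samples are granulated by closed Euclidean balls
   N_B(x) = {y : ‖x − y‖₂ ≤ δ} over a gene subset B. The positive region
   POS_B(D) collects samples whose whole neighborhood shares their class;
   the dependency degree γ_B = |POS_B|/|U| measures classification
   consistency. A greedy forward search repeatedly adds the gene with the
   largest significance SIG(a, B) = γ_{B∪{a}} − γ_B while that gain exceeds
   a floor (default 0.01). The radius δ is swept over a grid in [0, 2]
   (default step 0.01) and each reduct is scored by stratified
   cross-validated accuracy; the best-scoring radius wins, with ties going
   to the smaller panel, then the smaller radius.

Evaluation uses stratified k-fold cross-validation (default 10-fold) with a
linear SVM (or 1-NN), pooling confusion counts over folds; precision refers
to the designated positive class. `compare` pits the full pipeline against
its two ablations: PCA scoring alone and rough-set reduction without the
PCA filter.

## Worked example

Simulate a two-class study (60 samples, 200 genes: 6 informative at a 2 SD
class effect, 20 redundant copies, 174 noise genes), select a panel, and
evaluate it:

```sh
opca simulate --seed 1 --out-matrix X.csv --out-labels y.csv --out-truth truth.tsv
opca select --matrix X.csv --labels y.csv --sig-floor 0.01 --contrib 0.01 \
            --seed 1 --out sel.tsv
```

which prints

```
wrote 60 samples x 200 genes
selected 3 genes at radius 0.07 (dependency 1.000); CV accuracy 0.983, precision 0.968
```

i.e. three genes suffice to make every sample's neighborhood class-pure at
radius 0.07, and the panel classifies held-out samples at 98.3% accuracy /
96.8% positive-class precision under 10-fold CV. `sel.tsv` lists the genes
with their significance at acceptance and the cumulative dependency;
`sel.json` carries the full run report. Checking `truth.tsv` shows all three
are planted signal (noisy copies of informative genes). Compare against the
ablations with:

```sh
opca compare --matrix X.csv --labels y.csv --methods opca,pca,nrs --seed 1
```

A fixed radius can replace the sweep (`--delta 0.77`), matching published
per-dataset settings.

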