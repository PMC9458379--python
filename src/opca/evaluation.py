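"""Cross-validated evaluation, pipeline orchestration and method comparison.

The classification protocol is stratified k-fold cross-validation with a
linear support-vector classifier (default) or a 1-nearest-neighbor
alternative.  Precision refers to the designated positive class and both
metrics are pooled over folds from the summed confusion counts.

Feature selection runs once on the full dataset before cross-validation (the
panel is fixed across folds); ``nested=True`` re-selects inside each training
fold for an unbiased estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import ExpressionDataset, RunConfig
from .pca import PCAResult, fit_pca
from .rough_set import ReductResult, normalize_attributes, radius_search

__all__ = [
    "EvaluationReport",
    "compute_metrics",
    "cross_validate",
    "nested_cross_validate",
    "run_opca",
    "compare_selectors",
]

logger = logging.getLogger("opca")


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled cross-validation metrics plus per-fold confusion counts.

    ``per_fold`` rows are (TP, FP, FN, TN) with respect to the positive
    class; ``precision`` and ``accuracy`` are recomputed from the summed
    counts, so they are exactly consistent with ``per_fold``.
    """

    precision: float
    accuracy: float
    per_fold: tuple[tuple[int, int, int, int], ...]
    n_features_used: int
    classifier: str
    folds: int
    seed: int
    positive_class: str
    fallback_single_gene: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "accuracy": self.accuracy,
            "per_fold": [list(f) for f in self.per_fold],
            "n_features_used": self.n_features_used,
            "classifier": self.classifier,
            "folds": self.folds,
            "seed": self.seed,
            "positive_class": self.positive_class,
            "fallback_single_gene": self.fallback_single_gene,
        }


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """Positive-class precision TP/(TP+FP) and accuracy (TP+TN)/total.

    Precision is defined as 0 when no positive predictions were made.
    """
    counts = (tp, fp, fn, tn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts must not all be zero")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    accuracy = (tp + tn) / total
    return precision, accuracy


def _make_classifier(name: str):
    if name == "linear-svm":
        return SVC(kernel="linear", C=1.0)
    if name == "knn1":
        return KNeighborsClassifier(n_neighbors=1)
    raise ValueError(f"unknown classifier {name!r}")


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    config: RunConfig,
    *,
    positive_class: str | None = None,
    fallback_single_gene: bool = False,
) -> EvaluationReport:
    """Stratified k-fold CV of a fixed gene panel; deterministic given seed.

    ``X`` holds only the selected genes (samples x genes).  The classifier is
    refit on the training folds only; confusion counts are pooled across
    folds before computing precision and accuracy.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] < 1:
        raise ValueError("at least one selected gene is required")
    y = np.asarray(list(labels), dtype=object)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError("cross-validation requires exactly two classes")
    pos = positive_class if positive_class is not None else classes[1]
    if pos not in classes:
        raise ValueError(f"positive class {pos!r} not among {classes}")
    _, counts = np.unique(y.astype(str), return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"a class has only {counts.min()} samples; "
            f"use at most {counts.min()} folds"
        )

    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    per_fold = []
    for train, test in skf.split(X, y.astype(str)):
        clf = _make_classifier(config.classifier)
        clf.fit(X[train], y[train].astype(str))
        pred = clf.predict(X[test])
        truth = y[test].astype(str)
        tp = int(np.sum((pred == pos) & (truth == pos)))
        fp = int(np.sum((pred == pos) & (truth != pos)))
        fn = int(np.sum((pred != pos) & (truth == pos)))
        tn = int(np.sum((pred != pos) & (truth != pos)))
        per_fold.append((tp, fp, fn, tn))
    pooled = tuple(int(sum(f[i] for f in per_fold)) for i in range(4))
    precision, accuracy = compute_metrics(*pooled)
    return EvaluationReport(
        precision=precision,
        accuracy=accuracy,
        per_fold=tuple(per_fold),
        n_features_used=int(X.shape[1]),
        classifier=config.classifier,
        folds=config.cv_folds,
        seed=config.seed,
        positive_class=pos,
        fallback_single_gene=fallback_single_gene,
    )


def _search_reduct(
    dataset: ExpressionDataset,
    candidate_idx: np.ndarray,
    config: RunConfig,
) -> tuple[float, ReductResult]:
    """Radius search over candidates, scored by CV accuracy of each panel."""
    pos = dataset.positive_class(config.positive_class)
    norm = normalize_attributes(dataset.matrix[:, candidate_idx])
    y = dataset.label_array()

    def evaluate(reduct: ReductResult) -> float:
        cols = candidate_idx[list(reduct.selected)]
        rep = cross_validate(dataset.matrix[:, cols], y, config, positive_class=pos)
        return rep.accuracy

    delta, reduct = radius_search(
        norm, y, config.delta_grid, config.significance_floor, evaluator=evaluate
    )
    remapped = ReductResult(
        selected=tuple(int(candidate_idx[j]) for j in reduct.selected),
        significance_trace=reduct.significance_trace,
        dependency_trace=reduct.dependency_trace,
        delta_used=reduct.delta_used,
        final_dependency=reduct.final_dependency,
    )
    return delta, remapped


def run_opca(
    dataset: ExpressionDataset, config: RunConfig
) -> tuple[ReductResult, EvaluationReport, PCAResult]:
    """Full pipeline: PCA candidate filter -> radius-searched greedy reduct -> CV.

    Candidate genes come from the contribution-rate gate; the rough-set
    search sweeps the radius grid scoring each reduct by cross-validated
    accuracy.  An empty final reduct falls back to the single best-scoring
    candidate gene, flagged in the report.  Deterministic given the seed.
    """
    pca = fit_pca(dataset, config.contribution_threshold)
    logger.info("candidate genes after contribution filter: %d", pca.candidate_genes.size)
    delta, reduct = _search_reduct(dataset, pca.candidate_genes, config)
    logger.info("radius %.2f selected %d genes", delta, len(reduct.selected))

    fallback = False
    if not reduct.selected:
        best = int(pca.candidate_genes[np.argmax(pca.gene_scores[pca.candidate_genes])])
        reduct = ReductResult(
            selected=(best,),
            significance_trace=(0.0,),
            dependency_trace=(0.0,),
            delta_used=delta,
            final_dependency=0.0,
        )
        fallback = True
        logger.warning("empty reduct; falling back to top-scoring candidate gene %d", best)

    pos = dataset.positive_class(config.positive_class)
    report = cross_validate(
        dataset.matrix[:, list(reduct.selected)],
        dataset.label_array(),
        config,
        positive_class=pos,
        fallback_single_gene=fallback,
    )
    return reduct, report, pca


def nested_cross_validate(
    dataset: ExpressionDataset, config: RunConfig
) -> EvaluationReport:
    """Outer CV where gene selection is re-run inside every training fold.

    Unlike the default protocol, the test fold never influences which genes
    are selected, so the estimate is unbiased (and typically lower).  The
    inner selection uses the same configuration with the fold count capped
    by the smaller training-class size.
    """
    y = dataset.label_array()
    pos = dataset.positive_class(config.positive_class)
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    per_fold = []
    n_feat = []
    for train, test in skf.split(dataset.matrix, y.astype(str)):
        sub = ExpressionDataset(
            dataset.matrix[train],
            dataset.gene_ids,
            [dataset.sample_ids[i] for i in train],
            [dataset.labels[i] for i in train],
        )
        _, counts = np.unique(np.asarray(sub.labels), return_counts=True)
        inner = replace(config, cv_folds=min(config.cv_folds, int(counts.min())))
        reduct, _, _ = run_opca(sub, inner)
        cols = list(reduct.selected)
        n_feat.append(len(cols))
        clf = _make_classifier(config.classifier)
        clf.fit(dataset.matrix[np.ix_(train, cols)], y[train].astype(str))
        pred = clf.predict(dataset.matrix[np.ix_(test, cols)])
        truth = y[test].astype(str)
        tp = int(np.sum((pred == pos) & (truth == pos)))
        fp = int(np.sum((pred == pos) & (truth != pos)))
        fn = int(np.sum((pred != pos) & (truth == pos)))
        tn = int(np.sum((pred != pos) & (truth != pos)))
        per_fold.append((tp, fp, fn, tn))
    pooled = tuple(int(sum(f[i] for f in per_fold)) for i in range(4))
    precision, accuracy = compute_metrics(*pooled)
    return EvaluationReport(
        precision=precision,
        accuracy=accuracy,
        per_fold=tuple(per_fold),
        n_features_used=int(round(float(np.mean(n_feat)))),
        classifier=config.classifier,
        folds=config.cv_folds,
        seed=config.seed,
        positive_class=pos,
    )


def compare_selectors(
    dataset: ExpressionDataset,
    config: RunConfig,
    methods: tuple[str, ...] = ("opca", "pca", "nrs"),
) -> pd.DataFrame:
    """Selected-gene counts and CV metrics for OPCA and its two ablations.

    ``pca``: the top candidate genes by contribution score alone, capped at
    the OPCA reduct size (min 1).  ``nrs``: the radius-searched greedy reduct
    over all genes without the PCA filter.  All rows use the identical CV
    protocol.
    """
    valid = ("opca", "pca", "nrs")
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    for m in methods:
        if m not in valid:
            raise ValueError(f"unknown method {m!r}; valid methods are {list(valid)}")

    pos = dataset.positive_class(config.positive_class)
    y = dataset.label_array()
    # OPCA always runs: the PCA baseline's panel size is capped at its reduct size
    reduct, report, pca = run_opca(dataset, config)
    panels: dict[str, tuple[np.ndarray, EvaluationReport]] = {}
    panels["opca"] = (np.asarray(reduct.selected, dtype=int), report)

    if "pca" in methods:
        k = max(len(reduct.selected), 1)
        scores = pca.gene_scores
        order = np.lexsort((np.arange(scores.size), -scores))
        cols = np.sort(order[:k])
        rep = cross_validate(dataset.matrix[:, cols], y, config, positive_class=pos)
        panels["pca"] = (cols, rep)

    if "nrs" in methods:
        norm = normalize_attributes(dataset.matrix)

        def evaluate(r: ReductResult) -> float:
            return cross_validate(
                dataset.matrix[:, list(r.selected)], y, config, positive_class=pos
            ).accuracy

        _, nrs_reduct = radius_search(
            norm, y, config.delta_grid, config.significance_floor, evaluator=evaluate
        )
        cols = np.asarray(nrs_reduct.selected, dtype=int)
        if cols.size == 0:
            cols = np.asarray([int(np.argmax(pca.gene_scores))])
        rep = cross_validate(dataset.matrix[:, cols], y, config, positive_class=pos)
        panels["nrs"] = (cols, rep)

    rows = [
        {
            "method": m,
            "n_genes": int(panels[m][0].size),
            "precision": panels[m][1].precision,
            "accuracy": panels[m][1].accuracy,
        }
        for m in methods
    ]
    return pd.DataFrame(rows, columns=["method", "n_genes", "precision", "accuracy"])
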