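"""Covariance eigenstructure, contribution rates and candidate gene filtering.

The candidate filter keeps principal components whose contribution rate
(eigenvalue share of total variance) exceeds a threshold, scores every gene
by its contribution-weighted squared loadings on those components, and keeps
the genes whose renormalized score exceeds the same threshold.  This turns a
component-level variance gate into a gene set, which the downstream rough-set
reduction requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datasets import ExpressionDataset

__all__ = [
    "PCAResult",
    "compute_covariance",
    "eigendecompose",
    "contribution_rates",
    "gene_scores",
    "select_candidate_genes",
    "fit_pca",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the gene-gene covariance matrix.

    eigenvalues : descending, clipped at zero (variance units)
    loadings : orthonormal eigenvectors, one row per eigenvalue
    contribution_rates : eigenvalue / total variance, summing to 1
    gene_scores : per-gene share of retained variance, summing to 1
    candidate_genes : indices of genes whose score exceeds the threshold
    threshold : the contribution-rate gate that produced the candidates
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    contribution_rates: np.ndarray
    gene_scores: np.ndarray
    candidate_genes: np.ndarray
    threshold: float

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "contribution_rates": self.contribution_rates.tolist(),
            "gene_scores": self.gene_scores.tolist(),
            "candidate_genes": [int(i) for i in self.candidate_genes],
            "threshold": float(self.threshold),
        }


def compute_covariance(
    dataset: ExpressionDataset | np.ndarray, *, ddof: int = 0
) -> np.ndarray:
    """Gene-gene covariance H = (1/M) sum_k (x_k - mean)(x_k - mean)^T.

    The divisor is the sample count M (``ddof=0``); pass ``ddof=1`` for the
    unbiased estimator.  Requires at least two samples.
    """
    X = dataset.matrix if isinstance(dataset, ExpressionDataset) else np.asarray(dataset, float)
    M = X.shape[0]
    if M < 2:
        raise ValueError("covariance requires at least two samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    H = (Xc.T @ Xc) / (M - ddof)
    return (H + H.T) / 2.0  # enforce exact symmetry against rounding


def eigendecompose(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending, clipped at 0) and orthonormal loadings of H.

    Each eigenvector's sign is fixed so its largest-magnitude entry (lowest
    index on ties) is non-negative, making the decomposition reproducible.
    Loadings are returned as rows: ``loadings[k]`` pairs with
    ``eigenvalues[k]``.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(H, H.T, atol=_SYM_TOL, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    w, V = scipy.linalg.eigh((H + H.T) / 2.0)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    w = np.where(w < 0, np.where(w > -1e-10, 0.0, w), w)
    if (w < 0).any():
        w = np.clip(w, 0.0, None)  # larger negatives: still clip, H came in PSD-tol symmetric
    loadings = V.T.copy()
    for k in range(loadings.shape[0]):
        pivot = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, pivot] < 0:
            loadings[k] = -loadings[k]
    return w, loadings


def contribution_rates(eigenvalues: np.ndarray) -> np.ndarray:
    """c_k = beta_k / sum(beta); errors on an all-zero spectrum."""
    w = np.asarray(eigenvalues, dtype=float)
    if (w < 0).any():
        raise ValueError("eigenvalues must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate data: total variance is zero")
    return w / total


def gene_scores(
    eigenvalues: np.ndarray, loadings: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-gene variance share over components with contribution rate > threshold.

    s_j = sum_k c_k * loadings[k, j]^2 over retained components, renormalized
    to sum 1.  A gene loading zero on every retained component scores 0.
    """
    rates = contribution_rates(eigenvalues)
    keep = rates > threshold
    raw = rates[keep] @ (np.asarray(loadings)[keep] ** 2)
    total = raw.sum()
    return raw / total if total > 0 else raw


def select_candidate_genes(pca: "PCAResult | np.ndarray", threshold: float = 0.01) -> np.ndarray:
    """Indices of genes whose score exceeds the contribution threshold.

    Accepts a PCAResult or a raw score vector.  When no gene clears the gate,
    falls back to the top ceil(sqrt(m)) genes by score (ties broken toward the
    lower index) so the pipeline always has candidates to reduce.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    scores = pca.gene_scores if isinstance(pca, PCAResult) else np.asarray(pca, float)
    candidates = np.flatnonzero(scores > threshold)
    if candidates.size:
        return candidates
    m = scores.size
    k = math.ceil(math.sqrt(m))
    order = np.lexsort((np.arange(m), -scores))  # score desc, index asc on ties
    return np.sort(order[:k])


def fit_pca(
    dataset: ExpressionDataset, threshold: float = 0.01, *, ddof: int = 0
) -> PCAResult:
    """Full candidate-filter fit: covariance, eigenpairs, rates, gene scores."""
    H = compute_covariance(dataset, ddof=ddof)
    w, loadings = eigendecompose(H)
    rates = contribution_rates(w)
    scores = gene_scores(w, loadings, threshold)
    candidates = select_candidate_genes(scores, threshold)
    return PCAResult(
        eigenvalues=w,
        loadings=loadings,
        contribution_rates=rates,
        gene_scores=scores,
        candidate_genes=candidates,
        threshold=float(threshold),
    )
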