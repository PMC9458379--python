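"""Synthetic two-class expression matrices with planted gene roles.

The generator emulates the shape of two-class tumor microarray studies: a
few dozen samples split into two classes, a handful of informative genes
whose class means differ by ``effect_size`` standard deviations, noisy
copies of those genes (redundant), and a large majority of pure-noise genes.
Intensities live on a standardized Gaussian scale; the pipeline min-max
normalizes before distance computation, so only relative structure matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

__all__ = ["SyntheticSpec", "generate_dataset", "write_fixture"]

NEGATIVE_CLASS = "normal"
POSITIVE_CLASS = "tumor"  # lexicographically larger -> default positive class


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design for one synthetic dataset.

    ``effect_size`` is the class-mean separation of informative genes in SD
    units; redundant genes are cyclic noisy copies of informative parents
    with additive noise of ``redundancy_noise_sd``.  Defaults give a 60 x 200
    design with 6 informative, 20 redundant and 174 noise genes at a 2 SD
    effect.
    """

    n_pos: int = 30
    n_neg: int = 30
    n_informative: int = 6
    n_redundant: int = 20
    n_noise: int = 174
    effect_size: float = 2.0
    redundancy_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_informative", "n_redundant", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_redundant > 0 and self.n_informative < 1:
            raise ValueError("redundant genes require at least one informative parent")
        if self.n_genes < 1:
            raise ValueError("at least one gene is required")
        if self.n_pos + self.n_neg < 2:
            raise ValueError("at least two samples are required")
        if self.redundancy_noise_sd < 0:
            raise ValueError("redundancy_noise_sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    @property
    def n_samples(self) -> int:
        return self.n_pos + self.n_neg


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one dataset and its gene-role truth table.

    Informative gene: N(0,1) in the negative class, N(effect_size, 1) in the
    positive class.  Redundant gene: a cyclically assigned informative parent
    plus N(0, redundancy_noise_sd).  Noise gene: N(0,1) everywhere.  Gene
    order is shuffled deterministically by the seed; the truth table stays
    aligned with the shuffled gene ids and records each redundant gene's
    parent.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_genes
    is_pos = np.zeros(n, dtype=bool)
    is_pos[: spec.n_pos] = True
    labels = np.where(is_pos, POSITIVE_CLASS, NEGATIVE_CLASS)

    X = np.empty((n, m))
    roles = []
    parents = []
    col = 0
    informative_cols = []
    for _ in range(spec.n_informative):
        g = rng.normal(0.0, 1.0, size=n)
        g[is_pos] += spec.effect_size
        X[:, col] = g
        informative_cols.append(col)
        roles.append("informative")
        parents.append(-1)
        col += 1
    for r in range(spec.n_redundant):
        parent = informative_cols[r % spec.n_informative]
        X[:, col] = X[:, parent] + rng.normal(0.0, spec.redundancy_noise_sd, size=n)
        roles.append("redundant")
        parents.append(parent)
        col += 1
    for _ in range(spec.n_noise):
        X[:, col] = rng.normal(0.0, 1.0, size=n)
        roles.append("noise")
        parents.append(-1)
        col += 1

    perm = rng.permutation(m)
    X = X[:, perm]
    roles = [roles[p] for p in perm]
    # parent indices must refer to post-shuffle positions
    new_pos = np.empty(m, dtype=int)
    new_pos[perm] = np.arange(m)
    parents = [int(new_pos[parents[p]]) if parents[p] >= 0 else -1 for p in perm]

    width = len(str(m))
    gene_ids = [f"g{i:0{width}d}" for i in range(m)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    dataset = ExpressionDataset(X, gene_ids, sample_ids, labels.tolist())
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "role": roles, "parent": parents}
    )
    return dataset, truth


def write_fixture(
    dataset: ExpressionDataset,
    truth: pd.DataFrame,
    matrix_path: str | Path,
    labels_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write matrix (genes-as-rows CSV), labels CSV and truth TSV.

    Round-trips through :func:`opca.datasets.load_dataset` with the default
    genes-rows orientation; identical seeds yield byte-identical files.
    """
    frame = pd.DataFrame(
        dataset.matrix.T, index=list(dataset.gene_ids), columns=list(dataset.sample_ids)
    )
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path)  # default repr round-trips floats exactly
    labels = pd.DataFrame(
        {"sample_id": list(dataset.sample_ids), "label": list(dataset.labels)}
    )
    labels.to_csv(labels_path, index=False)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
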