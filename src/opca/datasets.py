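"""Loading, validation and serialization of two-class expression data.

Expression matrices are delimited text (CSV/TSV) with one header row and one
identifier column.  Microarray matrices conventionally ship genes-as-rows, so
that is the default on-disk orientation; in memory every dataset is held
samples x genes.  Labels are a two-column delimited file mapping sample id to
one of exactly two class symbols.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "RunConfig",
    "load_dataset",
    "load_selection",
    "write_selection",
    "default_delta_grid",
]


def default_delta_grid() -> np.ndarray:
    """Neighborhood radius grid 0.00 .. 2.00 in steps of 0.01."""
    return np.round(np.arange(0.0, 2.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class ExpressionDataset:
    """A samples x genes expression matrix with a binary class label per sample.

    Attributes
    ----------
    matrix : ndarray, shape (n_samples, n_genes)
        Real-valued expression levels (arbitrary units, e.g. intensities).
    gene_ids : tuple of str
        Unique gene identifiers, one per column.
    sample_ids : tuple of str
        Unique sample identifiers, one per row.
    labels : tuple of str
        Class symbol per sample; exactly two distinct symbols must occur.
    """

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(c) for c in self.labels))
        if mat.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, m = mat.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids "
                f"and {len(self.labels)} labels"
            )
        if len(self.gene_ids) != m:
            raise ValueError(f"matrix has {m} columns but {len(self.gene_ids)} gene ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if not np.isfinite(mat).all():
            raise ValueError("expression matrix contains non-finite values")
        if len(set(self.labels)) != 2:
            raise ValueError(
                f"exactly two classes required, found {sorted(set(self.labels))}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> tuple[str, str]:
        """The two class symbols in sorted order."""
        a, b = sorted(set(self.labels))
        return a, b

    def positive_class(self, override: str | None = None) -> str:
        """Designated positive class: lexicographically larger unless overridden."""
        if override is not None:
            if override not in self.classes:
                raise ValueError(
                    f"positive class {override!r} not among classes {self.classes}"
                )
            return override
        return self.classes[1]

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def __eq__(self, other: object) -> bool:  # array fields need explicit compare
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
        )


@dataclass
class RunConfig:
    """Pipeline configuration.

    contribution_threshold : fraction in (0, 1)
        PCA contribution-rate gate applied to components and to the derived
        per-gene scores (default 1%).
    delta_grid : radii in [0, 2]
        Neighborhood radius candidates swept during reduct search.
    significance_floor : float >= 0
        Lower limit on the dependency gain a gene must deliver to enter the
        reduct (default 0.01).
    classifier : {"linear-svm", "knn1"}
    cv_folds : int >= 2
    seed : int
    orientation : {"genes-rows", "samples-rows"}
        On-disk orientation of the matrix file.
    positive_class : optional str
        Class treated as positive for precision; default is the
        lexicographically larger class symbol.
    impute : {"reject", "mean"}
        Missing-cell policy for the loader.
    """

    contribution_threshold: float = 0.01
    delta_grid: Sequence[float] = field(default_factory=default_delta_grid)
    significance_floor: float = 0.01
    classifier: str = "linear-svm"
    cv_folds: int = 10
    seed: int = 0
    orientation: str = "genes-rows"
    positive_class: str | None = None
    impute: str = "reject"

    def __post_init__(self) -> None:
        if not 0.0 < self.contribution_threshold < 1.0:
            raise ValueError("contribution_threshold must lie in (0, 1)")
        grid = np.asarray(list(self.delta_grid), dtype=float)
        if grid.size == 0:
            raise ValueError("delta_grid must be non-empty")
        if (grid < 0).any() or (grid > 2).any():
            raise ValueError("all radii must lie in [0, 2]")
        self.delta_grid = grid
        if self.significance_floor < 0:
            raise ValueError("significance_floor must be >= 0")
        if self.classifier not in ("linear-svm", "knn1"):
            raise ValueError("classifier must be 'linear-svm' or 'knn1'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.orientation not in ("genes-rows", "samples-rows"):
            raise ValueError("orientation must be 'genes-rows' or 'samples-rows'")
        if self.impute not in ("reject", "mean"):
            raise ValueError("impute must be 'reject' or 'mean'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_grid"] = [float(x) for x in np.asarray(self.delta_grid)]
        return d


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def _coerce_numeric(frame: pd.DataFrame, config: RunConfig) -> np.ndarray:
    """Convert a string frame to floats, locating the first bad cell.

    Coordinates in error messages are 1-based positions within the data block
    as stored on disk (header row and id column excluded).
    """
    values = frame.to_numpy(dtype=object)
    out = np.empty(values.shape, dtype=float)
    bad = np.zeros(values.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(values):
        try:
            out[i, j] = float(cell)
        except (TypeError, ValueError):
            out[i, j] = np.nan
            bad[i, j] = True
    missing = bad | ~np.isfinite(out)
    if missing.any():
        if config.impute == "reject":
            i, j = np.argwhere(missing)[0]
            raise ValueError(
                f"non-numeric or missing value {values[i, j]!r} at "
                f"row {i + 1}, column {j + 1}"
            )
        # per-gene mean imputation; genes are rows or columns per orientation
        axis = 1 if config.orientation == "genes-rows" else 0
        means = np.nanmean(np.where(missing, np.nan, out), axis=axis, keepdims=True)
        out = np.where(missing, np.broadcast_to(means, out.shape), out)
    return out


def load_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    config: RunConfig | None = None,
) -> ExpressionDataset:
    """Load a delimited expression matrix plus labels into samples x genes form.

    The matrix file has one header row and one id column; ``config.orientation``
    says whether rows are genes (default) or samples.  The labels file maps
    sample id to class symbol; every sample in the matrix must appear.
    """
    config = config or RunConfig()
    frame = _read_table(matrix_path)
    values = _coerce_numeric(frame, config)
    if config.orientation == "genes-rows":
        gene_ids = [str(g) for g in frame.index]
        sample_ids = [str(s) for s in frame.columns]
        matrix = values.T
    else:
        sample_ids = [str(s) for s in frame.index]
        gene_ids = [str(g) for g in frame.columns]
        matrix = values

    lab = _read_table(labels_path)
    label_map = {str(k): str(v) for k, v in lab.iloc[:, 0].items()}
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise ValueError(f"labels file is missing sample id {missing[0]!r}")
    labels = [label_map[s] for s in sample_ids]
    n_classes = len(set(labels))
    if n_classes != 2:
        raise ValueError(
            f"exactly two classes required, labels define {n_classes}: "
            f"{sorted(set(labels))}"
        )
    return ExpressionDataset(matrix, gene_ids, sample_ids, labels)


def write_selection(
    result,
    dataset: ExpressionDataset,
    path: str | Path,
    *,
    report_path: str | Path | None = None,
    config: RunConfig | None = None,
    report=None,
) -> None:
    """Write a selected gene panel as TSV plus an optional JSON run report.

    The TSV carries rank, gene_id, significance at acceptance time and the
    cumulative dependency after acceptance.  The JSON report records the
    configuration, the radius used, the full traces and evaluation metrics
    when available.
    """
    for idx in result.selected:
        if not 0 <= idx < dataset.n_genes:
            raise IndexError(f"gene index {idx} out of range for {dataset.n_genes} genes")
    rows = [
        {
            "rank": r + 1,
            "gene_id": dataset.gene_ids[idx],
            "significance": result.significance_trace[r],
            "cumulative_dependency": result.dependency_trace[r],
        }
        for r, idx in enumerate(result.selected)
    ]
    frame = pd.DataFrame(
        rows, columns=["rank", "gene_id", "significance", "cumulative_dependency"]
    )
    frame.to_csv(path, sep="\t", index=False)

    if report_path is not None:
        doc = {
            "delta": float(result.delta_used),
            "final_dependency": float(result.final_dependency),
            "selected_gene_ids": [dataset.gene_ids[i] for i in result.selected],
            "selected_indices": [int(i) for i in result.selected],
            "significance_trace": [float(x) for x in result.significance_trace],
            "dependency_trace": [float(x) for x in result.dependency_trace],
        }
        if config is not None:
            doc["config"] = config.to_dict()
        if report is not None:
            doc["evaluation"] = report.to_dict() if hasattr(report, "to_dict") else report
        Path(report_path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_selection(path: str | Path) -> pd.DataFrame:
    """Re-read a selection TSV written by :func:`write_selection`."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = ["rank", "gene_id", "significance", "cumulative_dependency"]
    if list(frame.columns) != expected:
        raise ValueError(f"selection file must have columns {expected}")
    return frame
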