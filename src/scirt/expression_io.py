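"""Expression-matrix containers, readers/writers and highly-variable-gene selection.

Internally everything is cells x genes: rows are the units that get ranked,
imputed and clustered. On-disk files in this field are usually genes x cells,
so the reader takes an explicit orientation flag and normalizes at the
boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

Orientation = Literal["genes_by_cells", "cells_by_genes"]
FileFormat = Literal["delimited", "matrix_market"]


class ValidationError(ValueError):
    """Raised when an input violates a data contract (negative entry, shape mismatch...)."""


@dataclass
class ExpressionMatrix:
    """Non-negative cells x genes expression matrix with cell/gene identifiers.

    Attributes
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Non-negative, finite expression values (counts or normalized reals).
    cell_ids : list of str
        Unique cell identifiers, one per row.
    gene_ids : list of str
        Unique gene identifiers, one per column.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        n_cells, n_genes = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene{j}" for j in range(n_genes)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        _check_nonnegative_finite(self.values)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.cell_ids), list(self.gene_ids))


@dataclass
class CellLabels:
    """Ground-truth cell-type labels, one per cell, for external clustering metrics."""

    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) < 1:
            raise ValidationError("labels must be non-empty")

    @property
    def n_types(self) -> int:
        return len(set(self.labels))

    def as_codes(self) -> np.ndarray:
        """Integer codes in order of first appearance."""
        seen: dict[str, int] = {}
        return np.array([seen.setdefault(lab, len(seen)) for lab in self.labels])

    def __len__(self) -> int:
        return len(self.labels)


def _check_nonnegative_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        idx = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(f"non-finite entry at {tuple(int(i) for i in idx)}")
    if np.any(values < 0):
        idx = np.argwhere(values < 0)[0]
        i, j = (int(k) for k in idx)
        raise ValidationError(
            f"negative entry {values[i, j]} at row {i}, column {j}: "
            "expression values must be non-negative"
        )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".mtx" else path
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def read_matrix(
    path: str | os.PathLike,
    orientation: Orientation = "genes_by_cells",
    format: FileFormat = "delimited",
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing to cells x genes.

    Parameters
    ----------
    path : path
        Delimited file (first row = column ids, first column = row ids,
        comma or tab separated) or Matrix Market ``.mtx`` with sidecar
        ``<stem>.rows.txt`` / ``<stem>.cols.txt`` id files.
    orientation : {"genes_by_cells", "cells_by_genes"}
        How rows/columns of the on-disk matrix are to be interpreted.
        ``genes_by_cells`` (the common convention for published expression
        tables) is transposed on read.
    format : {"delimited", "matrix_market"}

    Returns
    -------
    ExpressionMatrix
        Always cells x genes, regardless of on-disk orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if format == "delimited":
        first_line = ""
        with open(path) as fh:
            first_line = fh.readline()
        sep = "\t" if first_line.count("\t") > first_line.count(",") else ","
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        values = df.to_numpy(dtype=float)
        row_ids = [str(x) for x in df.index]
        col_ids = [str(x) for x in df.columns]
    elif format == "matrix_market":
        mat = mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        rows_path, cols_path = _sidecar_paths(path)
        row_ids = rows_path.read_text().splitlines() if rows_path.exists() else []
        col_ids = cols_path.read_text().splitlines() if cols_path.exists() else []
    else:
        raise ValidationError(f"unknown format {format!r}")

    _check_nonnegative_finite(values)
    if orientation == "genes_by_cells":
        values = values.T
        cell_ids, gene_ids = col_ids, row_ids
    else:
        cell_ids, gene_ids = row_ids, col_ids
    return ExpressionMatrix(values, list(cell_ids), list(gene_ids))


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    format: FileFormat = "delimited",
    orientation: Orientation = "cells_by_genes",
) -> None:
    """Write an expression matrix so that ``read_matrix`` inverts it exactly.

    Delimited output stores full-precision floats; Matrix Market output
    stores only nonzeros in coordinate format plus sidecar id files.
    """
    path = Path(path)
    values = matrix.values
    row_ids, col_ids = matrix.cell_ids, matrix.gene_ids
    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = matrix.gene_ids, matrix.cell_ids
    if format == "delimited":
        df = pd.DataFrame(values, index=row_ids, columns=col_ids)
        df.to_csv(path, float_format="%.17g")
    elif format == "matrix_market":
        mmwrite(str(path), sparse.coo_matrix(values))
        rows_path, cols_path = _sidecar_paths(path)
        rows_path.write_text("\n".join(row_ids) + ("\n" if row_ids else ""))
        cols_path.write_text("\n".join(col_ids) + ("\n" if col_ids else ""))
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_labels(path: str | os.PathLike) -> CellLabels:
    """Read one label per line, in cell order."""
    text = Path(path).read_text()
    labels = [line.strip() for line in text.splitlines() if line.strip()]
    return CellLabels(labels)


def write_labels(labels: CellLabels | Sequence[str], path: str | os.PathLike) -> None:
    seq = labels.labels if isinstance(labels, CellLabels) else [str(x) for x in labels]
    Path(path).write_text("\n".join(seq) + "\n")


def select_hvg(
    matrix: ExpressionMatrix, n_top: int, log1p: bool = False
) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes (unbiased sample variance across cells).

    Gene order among the selected genes follows the original matrix; variance
    ties are broken by original gene order. ``n_top`` larger than the number
    of genes returns the matrix unchanged. Values are never transformed; with
    ``log1p=True`` the *ranking* is computed on log1p values but the returned
    matrix keeps the values as read.
    """
    if n_top < 1:
        raise ValidationError(f"n_top must be >= 1, got {n_top}")
    s = matrix.n_genes
    if n_top >= s:
        return matrix.copy()
    data = np.log1p(matrix.values) if log1p else matrix.values
    variances = np.var(data, axis=0, ddof=1) if matrix.n_cells > 1 else np.zeros(s)
    # stable argsort on negated variance keeps original order among ties
    top = np.sort(np.argsort(-variances, kind="stable")[:n_top])
    return ExpressionMatrix(
        matrix.values[:, top].copy(),
        list(matrix.cell_ids),
        [matrix.gene_ids[j] for j in top],
    )
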