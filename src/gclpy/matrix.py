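"""Expression-matrix container and CSV I/O.

The canonical on-disk format is a plain CSV with gene identifiers in the
first column, cell identifiers in the header row, and nonnegative expression
values in the body (genes as rows, cells as columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "load_expression_csv"]


@dataclass
class ExpressionMatrix:
    """A genes x cells nonnegative expression matrix with labels.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_cells)``; all entries finite and >= 0.
    gene_ids
        Unique gene labels, one per row.
    cell_ids
        Unique cell labels, one per column.
    """

    values: np.ndarray
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x cells array")
        n, m = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{i:04d}" for i in range(n)], dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{j:04d}" for j in range(m)], dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.cell_ids) != m:
            raise ValueError("cell_ids length does not match number of columns")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != m:
            raise ValueError("duplicate cell identifiers")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite entry at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative entry at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_cells(self, index) -> "ExpressionMatrix":
        """Subset by cell positions (integer array/list or boolean mask)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index], self.gene_ids.copy(), self.cell_ids[index]
        )

    def select_genes(self, index) -> "ExpressionMatrix":
        """Subset by gene positions (integer array/list or boolean mask)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index, :], self.gene_ids[index], self.cell_ids.copy()
        )

    def drop_cells(self, cell_labels) -> "ExpressionMatrix":
        """Remove the named cells, preserving the order of the rest."""
        drop = set(cell_labels)
        keep = np.array([c not in drop for c in self.cell_ids], dtype=bool)
        return self.select_cells(keep)

    def cell_index(self, cell_label) -> int:
        hits = np.nonzero(self.cell_ids == cell_label)[0]
        if len(hits) == 0:
            raise KeyError(f"unknown cell {cell_label!r}")
        return int(hits[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "gene"
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(object), df.columns.to_numpy(object))


def load_expression_csv(path, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression CSV (first column gene IDs, header row cell IDs).

    Set ``transpose=True`` for tables written cells-as-rows. Raises
    ``ValueError`` with the offending coordinates for negative or
    non-numeric entries, and for duplicate gene IDs or ragged rows
    (pandas reports the row for the latter).
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.size == 0:
        raise ValueError(f"empty expression table in {path}")
    if transpose:
        df = df.T
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        i, j = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric entry at gene {df.index[i]!r}, cell {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix.from_dataframe(bad)
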