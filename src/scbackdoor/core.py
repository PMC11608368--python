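"""Core domain types and I/O for labeled single-cell expression matrices.

The central container is :class:`LabeledExpressionMatrix`: a cells × genes
matrix of non-negative expression values together with unique cell and gene
identifiers and one categorical cell-type label per cell.  All downstream
operations (poisoning, training, defenses) are defined on this container and
are agnostic to whether the values are raw counts or normalized expression —
thresholds are always interpreted on the scale of the stored values.

Supported on-disk encodings:

* ``h5ad`` — AnnData with cells as observations, genes as variables, labels
  in an ``obs`` column (default ``"celltype"``).
* ``mtx_dir`` — CellRanger-style directory: ``matrix.mtx`` (genes × cells,
  MatrixMarket coordinate; transposed on read), ``barcodes.tsv``,
  ``features.tsv``, plus a ``labels.tsv`` sidecar (one label per barcode).
* ``csv`` — dense table, cells as rows: first column ``cell_id``, last
  column ``label``, one column per gene in between.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "LabeledExpressionMatrix",
    "LabelVector",
    "ValidationError",
    "read_matrix",
    "write_matrix",
    "sequencing_depth",
    "MATRIX_FORMATS",
]

MATRIX_FORMATS = ("h5ad", "mtx_dir", "csv")

MatrixLike = Union[np.ndarray, sp.spmatrix]


class ValidationError(ValueError):
    """Raised when a matrix or label vector violates a structural invariant."""


def _as_2d(values: MatrixLike) -> MatrixLike:
    if sp.issparse(values):
        return values.tocsr()
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValidationError(f"expression values must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class LabeledExpressionMatrix:
    """Cells × genes expression values with per-cell categorical labels.

    Parameters
    ----------
    values
        Non-negative expression matrix, dense ndarray or scipy sparse
        (stored as CSR).  Rows are cells, columns are genes.
    cell_ids, gene_ids
        Unique string identifiers for rows / columns.
    labels
        One cell-type string per cell; at least two distinct labels must be
        present so that classification is defined.
    """

    values: MatrixLike
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = np.asarray([str(l) for l in np.asarray(self.labels).ravel()], dtype=object)
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"row mismatch: {n} rows, {len(self.cell_ids)} cell_ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.gene_ids) != g:
            raise ValidationError(f"column mismatch: {g} columns, {len(self.gene_ids)} gene_ids")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene_ids are not unique")
        data = self.values.data if sp.issparse(self.values) else self.values
        data = np.asarray(data)
        bad = ~np.isfinite(data) | (data < 0)
        if bad.any():
            coords = self._offending_coordinates(10)
            raise ValidationError(
                f"values must be finite and >= 0; offending (cell, gene) coordinates "
                f"(first {len(coords)}): {coords}"
            )
        if len(set(self.labels.tolist())) < 2:
            raise ValidationError("at least 2 distinct labels are required for classification")

    def _offending_coordinates(self, limit: int) -> list[tuple[int, int]]:
        vals = self.to_dense()
        with np.errstate(invalid="ignore"):
            rows, cols = np.where(~np.isfinite(vals) | (vals < 0))
        return list(zip(rows.tolist()[:limit], cols.tolist()[:limit]))

    # -- basic accessors --------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def to_dense(self) -> np.ndarray:
        """Dense float view of the values (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def row(self, i: int) -> np.ndarray:
        """Dense 1-D expression vector of cell ``i``."""
        if sp.issparse(self.values):
            return np.asarray(self.values.getrow(i).todense()).ravel()
        return np.asarray(self.values[i]).ravel()

    def is_integer(self) -> bool:
        """True if every stored value is a whole number (a count matrix)."""
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        data = np.asarray(data)
        if data.size == 0:
            return True
        if np.issubdtype(data.dtype, np.integer):
            return True
        return bool(np.all(data == np.floor(data)))

    def copy(self) -> "LabeledExpressionMatrix":
        return LabeledExpressionMatrix(
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            labels=self.labels.copy(),
        )

    def subset_cells(self, indices: Sequence[int]) -> "LabeledExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return LabeledExpressionMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            labels=self.labels[idx],
        )

    def equals(self, other: "LabeledExpressionMatrix", rtol: float = 0.0) -> bool:
        """Structural equality; ``rtol`` allows a relative value tolerance."""
        if (
            self.cell_ids != other.cell_ids
            or self.gene_ids != other.gene_ids
            or self.labels.tolist() != other.labels.tolist()
        ):
            return False
        a, b = self.to_dense(), other.to_dense()
        if rtol == 0.0:
            return bool(np.array_equal(a, b))
        return bool(np.allclose(a, b, rtol=rtol, atol=0.0))


@dataclass
class LabelVector:
    """An ordered vector of categorical labels plus its class universe."""

    entries: np.ndarray
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray([str(e) for e in np.asarray(self.entries).ravel()], dtype=object)
        if not self.classes:
            self.classes = sorted(set(self.entries.tolist()))
        else:
            self.classes = [str(c) for c in self.classes]
            unknown = set(self.entries.tolist()) - set(self.classes)
            if unknown:
                raise ValidationError(f"entries outside declared classes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.entries)


def sequencing_depth(m: LabeledExpressionMatrix) -> np.ndarray:
    """Per-cell sequencing depth: the row sum of the expression values."""
    if sp.issparse(m.values):
        return np.asarray(m.values.sum(axis=1)).ravel()
    return np.asarray(m.values).sum(axis=1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(
    path: Union[str, os.PathLike],
    format: str,
    label_key: str = "celltype",
) -> LabeledExpressionMatrix:
    """Read a labeled expression matrix from one of the supported encodings.

    ``label_key`` selects the per-cell annotation column for ``h5ad``; the
    other formats carry labels in a fixed position (last CSV column,
    ``labels.tsv`` sidecar).
    """
    path = Path(path)
    if format == "h5ad":
        return _read_h5ad(path, label_key)
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}; expected one of {MATRIX_FORMATS}")


def write_matrix(
    m: LabeledExpressionMatrix,
    path: Union[str, os.PathLike],
    format: str,
    label_key: str = "celltype",
) -> Path:
    """Write ``m`` so that ``read_matrix`` recovers it (round-trip identity)."""
    path = Path(path)
    if format == "h5ad":
        _write_h5ad(m, path, label_key)
    elif format == "mtx_dir":
        _write_mtx_dir(m, path)
    elif format == "csv":
        _write_csv(m, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {MATRIX_FORMATS}")
    return path


def _read_h5ad(path: Path, label_key: str) -> LabeledExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if label_key not in adata.obs.columns:
        raise KeyError(
            f"label column {label_key!r} not found in obs; available keys: "
            f"{list(adata.obs.columns)}"
        )
    values = adata.X
    if sp.issparse(values):
        values = values.tocsr()
    else:
        values = np.asarray(values)
    return LabeledExpressionMatrix(
        values=values,
        cell_ids=list(adata.obs_names),
        gene_ids=list(adata.var_names),
        labels=np.asarray(adata.obs[label_key].astype(str)),
    )


def _write_h5ad(m: LabeledExpressionMatrix, path: Path, label_key: str) -> None:
    import anndata as ad

    obs = pd.DataFrame({label_key: pd.Categorical(m.labels.tolist())},
                       index=pd.Index(m.cell_ids, name="cell_id"))
    var = pd.DataFrame(index=pd.Index(m.gene_ids, name="gene_id"))
    adata = ad.AnnData(X=m.values.copy(), obs=obs, var=var)
    path.parent.mkdir(parents=True, exist_ok=True)
    adata.write_h5ad(path)


def _read_mtx_dir(path: Path) -> LabeledExpressionMatrix:
    from scipy.io import mmread

    mtx = mmread(path / "matrix.mtx")  # genes x cells on disk
    values = sp.csr_matrix(mtx).T.tocsr()
    barcodes = (path / "barcodes.tsv").read_text().splitlines()
    features = (path / "features.tsv").read_text().splitlines()
    labels = (path / "labels.tsv").read_text().splitlines()
    if len(labels) != len(barcodes):
        raise ValidationError(
            f"labels.tsv has {len(labels)} entries for {len(barcodes)} barcodes"
        )
    return LabeledExpressionMatrix(
        values=values, cell_ids=barcodes, gene_ids=features, labels=np.asarray(labels)
    )


def _write_mtx_dir(m: LabeledExpressionMatrix, path: Path) -> None:
    from scipy.io import mmwrite

    path.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(m.values).T  # genes x cells, CellRanger convention
    fld = "integer" if m.is_integer() else "real"
    if fld == "integer":
        coo = coo.astype(np.int64)
    mmwrite(str(path / "matrix.mtx"), coo, field=fld)
    (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    (path / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")
    (path / "labels.tsv").write_text("\n".join(m.labels.tolist()) + "\n")


def _read_csv(path: Path) -> LabeledExpressionMatrix:
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 3:
        raise ValidationError("CSV needs cell_id, >=1 gene column, and a label column")
    cell_ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, -1].astype(str).to_numpy()
    gene_ids = [str(c) for c in df.columns[1:-1]]
    values = df.iloc[:, 1:-1].to_numpy()
    if np.all(values == np.floor(values)):
        values = values.astype(np.int64)
    return LabeledExpressionMatrix(
        values=values, cell_ids=cell_ids, gene_ids=gene_ids, labels=labels
    )


def _write_csv(m: LabeledExpressionMatrix, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = m.to_dense()
    if m.is_integer():
        vals = vals.astype(np.int64)
    df = pd.DataFrame(vals, columns=m.gene_ids)
    df.insert(0, "cell_id", m.cell_ids)
    df["label"] = m.labels.tolist()
    df.to_csv(path, index=False)
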