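"""Count-matrix I/O and input preprocessing.

The in-memory container is :class:`CountMatrix`: a dense cells × genes array of
non-negative integer counts plus unique cell/gene identifiers. Two on-disk
formats are supported:

* Matrix Market exchange format (``.mtx``) with companion identifier files
  ``<path>.rownames.txt`` / ``<path>.colnames.txt``. Following the dominant
  public convention the on-disk orientation defaults to genes-as-rows and is
  transposed on load; pass ``orientation="cells-as-rows"`` when the file is
  already cell-major.
* Dense delimited text (tab or comma, sniffed from the header line): header row
  of gene identifiers, first column of cell identifiers.

Preprocessing is deliberately minimal — optional per-cell library-size
normalization followed by log1p — because the likelihood is always evaluated
against the *raw* counts; the transforms only shape the encoder input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import ValidationError

__all__ = [
    "CountMatrix",
    "CovariateTable",
    "PreprocessSpec",
    "read_counts",
    "write_counts",
    "preprocess",
    "export_denoised",
]


@dataclass
class CountMatrix:
    """Cells × genes non-negative integer counts with row/column identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"{n_cells} rows but {len(self.cell_ids)} cell identifiers"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"{n_genes} columns but {len(self.gene_ids)} gene identifiers"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        _validate_counts(self.values, self.cell_ids, self.gene_ids)
        self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Per-cell total count (row sums)."""
        return self.values.sum(axis=1)

    def drop_zero_cells(self) -> "CountMatrix":
        """Return a copy without zero-library cells (warns when any are dropped)."""
        lib = self.library_sizes()
        keep = lib > 0
        if keep.all():
            return self
        dropped = [c for c, k in zip(self.cell_ids, keep) if not k]
        if not keep.any():
            raise ValidationError(
                f"zero library size for all {self.n_cells} cells"
            )
        warnings.warn(
            f"dropping {len(dropped)} cell(s) with zero library size: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        return CountMatrix(
            self.values[keep],
            [c for c, k in zip(self.cell_ids, keep) if k],
            self.gene_ids,
        )


def _validate_counts(values: np.ndarray, cell_ids, gene_ids) -> None:
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count matrix must be numeric")
    neg = np.argwhere(values < 0)
    if neg.size:
        c, g = neg[0]
        raise ValidationError(
            f"negative count at cell {cell_ids[c]!r}, gene {gene_ids[g]!r}"
        )
    if not np.issubdtype(values.dtype, np.integer):
        frac = np.argwhere(values != np.floor(values))
        if frac.size:
            c, g = frac[0]
            raise ValidationError(
                f"non-integer count at cell {cell_ids[c]!r}, gene {gene_ids[g]!r}"
            )


@dataclass
class CovariateTable:
    """Cells × k numeric covariates with column names."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("covariate table must be two-dimensional")
        if self.values.shape[1] != len(self.names):
            raise ValidationError("covariate name count does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("covariate table contains non-finite entries")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class PreprocessSpec:
    """Flags for the optional encoder-input transforms (applied to a copy)."""

    log_transform: bool = False
    library_normalize: bool = False


def _companion_paths(path: Path) -> tuple[Path, Path]:
    return Path(str(path) + ".rownames.txt"), Path(str(path) + ".colnames.txt")


def read_counts(
    path,
    format: str | None = None,
    orientation: str = "genes-as-rows",
    drop_zero_cells: bool = True,
) -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path : path-like
        ``.mtx`` file (with ``.rownames.txt``/``.colnames.txt`` companions) or a
        dense delimited text file.
    format : {"mtx", "dense-delimited"}, optional
        Inferred from the suffix when omitted.
    orientation : {"genes-as-rows", "cells-as-rows"}
        Declared on-disk orientation for ``mtx`` files (dense files are always
        cells-as-rows with a gene header).
    drop_zero_cells : bool
        Drop zero-library cells with a warning; if every cell is empty a
        :class:`~zipo.exceptions.ValidationError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "dense-delimited"
    if format == "mtx":
        rows_path, cols_path = _companion_paths(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"missing identifier companion file {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        if orientation == "genes-as-rows":
            cm = CountMatrix(np.asarray(mat).T, col_ids, row_ids)
        elif orientation == "cells-as-rows":
            cm = CountMatrix(np.asarray(mat), row_ids, col_ids)
        else:
            raise ValidationError(f"unknown orientation {orientation!r}")
    elif format == "dense-delimited":
        sep = _sniff_sep(path)
        df = pd.read_csv(path, sep=sep, index_col=0)
        cm = CountMatrix(df.to_numpy(), list(df.index), list(df.columns))
    else:
        raise ValidationError(f"unknown format {format!r}")
    if drop_zero_cells:
        cm = cm.drop_zero_cells()
    return cm


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def write_counts(
    X: CountMatrix,
    path,
    format: str | None = None,
    orientation: str = "genes-as-rows",
) -> None:
    """Write a count matrix in either supported format (round-trips with
    :func:`read_counts`)."""
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "dense-delimited"
    if format == "mtx":
        rows_path, cols_path = _companion_paths(path)
        if orientation == "genes-as-rows":
            mat, row_ids, col_ids = X.values.T, X.gene_ids, X.cell_ids
        elif orientation == "cells-as-rows":
            mat, row_ids, col_ids = X.values, X.cell_ids, X.gene_ids
        else:
            raise ValidationError(f"unknown orientation {orientation!r}")
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(mat))
        rows_path.write_text("\n".join(row_ids) + "\n")
        cols_path.write_text("\n".join(col_ids) + "\n")
    elif format == "dense-delimited":
        sep = "\t" if path.suffix != ".csv" else ","
        df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ValidationError(f"unknown format {format!r}")


def preprocess(X: CountMatrix, spec: PreprocessSpec) -> np.ndarray:
    """Build the encoder input matrix from raw counts.

    Order is normalize-then-log (the standard CPM-then-log convention): with
    ``library_normalize`` each row is divided by its library size; with
    ``log_transform`` log1p is applied afterwards. Raw counts are never
    modified — the likelihood always sees the original integers.
    """
    out = X.values.astype(np.float64)
    if spec.library_normalize:
        lib = out.sum(axis=1, keepdims=True)
        if np.any(lib == 0):
            idx = int(np.argwhere(lib.ravel() == 0)[0][0])
            raise ValidationError(
                f"zero library size for cell {X.cell_ids[idx]!r}; "
                "filter empty cells before library normalization"
            )
        out = out / lib
    if spec.log_transform:
        out = np.log1p(out)
    return out


def export_denoised(X: CountMatrix, dist, path, zero_prob_path=None) -> None:
    """Write the denoised rate matrix ``m = l·μ`` and the zero-probability
    matrix as dense delimited files with identifiers preserved.

    ``zero_prob_path`` defaults to ``<path>.zeroprob<suffix>``.
    """
    path = Path(path)
    m = dist.mean_rate()
    z = dist.zero_prob()
    if m.shape != X.values.shape:
        raise ValidationError(
            f"distribution shape {m.shape} does not match counts {X.values.shape}"
        )
    if zero_prob_path is None:
        zero_prob_path = path.with_suffix(".zeroprob" + path.suffix)
    sep = "," if path.suffix == ".csv" else "\t"
    pd.DataFrame(m, index=X.cell_ids, columns=X.gene_ids).to_csv(path, sep=sep)
    pd.DataFrame(z, index=X.cell_ids, columns=X.gene_ids).to_csv(
        zero_prob_path, sep=sep
    )
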