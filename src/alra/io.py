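"""Reading and writing expression matrices.

Supported formats:

* ``mtx_10x`` — a Matrix Market file plus ``genes.tsv``/``features.tsv`` and
  ``barcodes.tsv`` sidecars (the 10x Genomics triplet, optionally gzipped).
  On disk the matrix is conventionally genes x cells; orientation is resolved
  against the sidecar lengths and the matrix is returned cells-in-rows.
* ``csv`` / ``tsv`` — a delimited table with gene names in the header row and
  cell barcodes in the first column (or the transpose, with
  ``genes_in_rows=True``).

Duplicate gene symbols are disambiguated with numeric suffixes (".1", ".2",
...), never rejected, since repeated symbols are common in real annotations.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._exceptions import ConsistencyError, FormatError, ValidationError
from .containers import CountMatrix
from .core import ImputationResult

__all__ = ["read_counts", "write_imputed", "deduplicate_ids"]

_SIDE_GENES = ("genes.tsv", "features.tsv", "genes.tsv.gz", "features.tsv.gz")
_SIDE_BARCODES = ("barcodes.tsv", "barcodes.tsv.gz")
_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")


def deduplicate_ids(ids) -> list:
    """Append ".1", ".2", ... to repeated identifiers, first occurrence kept."""
    seen: dict = {}
    out = []
    for name in ids:
        name = str(name)
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _find(directory: Path, names, component: str) -> Path:
    for name in names:
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FormatError(
        f"missing {component} file in {directory} (looked for {', '.join(names)})"
    )


def _read_mtx_10x(path: Path) -> CountMatrix:
    if path.is_dir():
        directory, mtx = path, _find(path, _MTX_NAMES, "matrix")
    else:
        directory, mtx = path.parent, path
    genes_file = _find(directory, _SIDE_GENES, "genes/features")
    barcodes_file = _find(directory, _SIDE_BARCODES, "barcodes")

    matrix = scipy.io.mmread(str(mtx)).tocsr()
    genes = pd.read_csv(genes_file, sep="\t", header=None)
    # 2-column (id, symbol) and 3-column (id, symbol, type) dialects both
    # carry the symbol in column 1; a 1-column file is symbols only.
    gene_ids = genes.iloc[:, 1 if genes.shape[1] >= 2 else 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)
    cell_ids = barcodes.iloc[:, 0].astype(str).tolist()

    n_rows, n_cols = matrix.shape
    if (n_rows, n_cols) == (len(gene_ids), len(cell_ids)):
        matrix = matrix.T.tocsr()  # genes-in-rows on disk (10x convention)
    elif (n_rows, n_cols) == (len(cell_ids), len(gene_ids)):
        pass
    else:
        raise ConsistencyError(
            f"matrix is {n_rows} x {n_cols} but sidecars list "
            f"{len(gene_ids)} genes and {len(cell_ids)} barcodes"
        )
    return CountMatrix(
        values=matrix, cell_ids=cell_ids, gene_ids=deduplicate_ids(gene_ids)
    )


def _read_delimited(path: Path, sep: str, genes_in_rows: bool) -> CountMatrix:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if genes_in_rows:
        frame = frame.T
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path} contains non-numeric entries")
    return CountMatrix(
        values=values,
        cell_ids=deduplicate_ids(frame.index.astype(str)),
        gene_ids=deduplicate_ids(frame.columns.astype(str)),
    )


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_10x"
    suffixes = [s.lower() for s in path.suffixes]
    if ".mtx" in suffixes:
        return "mtx_10x"
    if ".tsv" in suffixes or ".txt" in suffixes:
        return "tsv"
    if ".csv" in suffixes:
        return "csv"
    raise FormatError(f"cannot infer format of {path}; pass format explicitly")


def read_counts(path, format: str | None = None, genes_in_rows: bool = False) -> CountMatrix:
    """Read a count matrix, returning it cells-in-rows regardless of the
    on-disk orientation.

    ``format`` is one of ``mtx_10x``, ``csv``, ``tsv`` (inferred from the
    path when omitted). ``genes_in_rows`` declares the orientation of a
    delimited file whose rows are genes; for ``mtx_10x`` orientation is
    resolved from the sidecar lengths.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    format = format or _infer_format(path)
    if format == "mtx_10x":
        return _read_mtx_10x(path)
    if format in ("csv", "tsv"):
        return _read_delimited(path, "," if format == "csv" else "\t", genes_in_rows)
    raise FormatError(f"unknown format {format!r}")


def _matrix_and_ids(result):
    if isinstance(result, ImputationResult):
        m = result.imputed
        cells = result.cell_ids or [f"cell_{i}" for i in range(m.shape[0])]
        genes = result.gene_ids or [f"gene_{j}" for j in range(m.shape[1])]
        return m, cells, genes
    if isinstance(result, CountMatrix):
        return result.values, result.cell_ids, result.gene_ids
    m = result
    return (
        m,
        [f"cell_{i}" for i in range(m.shape[0])],
        [f"gene_{j}" for j in range(m.shape[1])],
    )


def write_imputed(result, path, format: str = "mtx") -> None:
    """Write an imputed matrix (or any cells x genes matrix).

    ``mtx`` writes a 10x-style triplet (genes x cells ``matrix.mtx`` +
    ``genes.tsv`` + ``barcodes.tsv``) into the directory ``path``; ``csv``
    writes a cell-major table with gene ids as the header row.
    """
    matrix, cell_ids, gene_ids = _matrix_and_ids(result)
    path = Path(path)
    try:
        if format == "mtx":
            path.mkdir(parents=True, exist_ok=True)
            m = matrix if sp.issparse(matrix) else sp.csr_matrix(np.asarray(matrix))
            scipy.io.mmwrite(str(path / "matrix.mtx"), m.T.tocoo(), precision=10)
            pd.Series(gene_ids).to_csv(
                path / "genes.tsv", sep="\t", header=False, index=False
            )
            pd.Series(cell_ids).to_csv(
                path / "barcodes.tsv", sep="\t", header=False, index=False
            )
        elif format == "csv":
            dense = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
            pd.DataFrame(dense, index=cell_ids, columns=gene_ids).to_csv(path)
        else:
            raise FormatError(f"unknown output format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write to {path}: {exc}") from exc
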