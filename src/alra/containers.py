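"""In-memory containers for expression matrices.

The internal orientation everywhere in this package is **cells in rows,
genes in columns**; per-gene operations are per-column operations. Orientation
of on-disk files is resolved at the I/O boundary (:mod:`alra.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._exceptions import ValidationError

__all__ = ["CountMatrix", "NormalizedMatrix"]


def _as_2d(values):
    if sp.issparse(values):
        return values.tocsr()
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-d matrix, got ndim={arr.ndim}")
    return arr


def _check_nonnegative(values, what: str) -> None:
    data = values.data if sp.issparse(values) else values
    if not np.issubdtype(np.asarray(data).dtype, np.number):
        raise ValidationError(f"{what} contains non-numeric entries")
    if data.size and np.nanmin(data) < 0:
        raise ValidationError(f"{what} contains negative entries")
    if np.isnan(data).any():
        raise ValidationError(f"{what} contains NaN entries")


def _check_ids(ids, n: int, what: str, unique: bool = True):
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValidationError(f"{len(ids)} {what} for {n} matrix {what.split('_')[0]}s")
    if unique and len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what}")
    return ids


@dataclass
class CountMatrix:
    """Raw non-negative expression counts, cells in rows.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` dense array or scipy sparse matrix; sparse
        inputs are kept sparse (CSR).
    cell_ids
        Unique cell barcodes, one per row.
    gene_ids
        Unique gene symbols, one per column (disambiguated upstream if the
        source annotation repeated a symbol).
    """

    values: object
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    layout: str = "cells-in-rows"

    def __post_init__(self):
        self.values = _as_2d(self.values)
        _check_nonnegative(self.values, "count matrix")
        n_cells, n_genes = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(n_genes)]
        self.cell_ids = _check_ids(self.cell_ids, n_cells, "cell_ids")
        self.gene_ids = _check_ids(self.gene_ids, n_genes, "gene_ids")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class NormalizedMatrix:
    """Library-normalized, log-transformed expression (cells in rows).

    Entries are ``log(1 + alpha * c_ij / sum_g c_ig)`` with the natural
    logarithm, so an entry is exactly 0 iff the raw count was 0 and the
    sparsity pattern of the counts is preserved.
    """

    values: object
    cell_ids: list
    gene_ids: list
    alpha: float = 10_000.0
    pseudocount: float = 1.0
    log_base: str = "e"

    def __post_init__(self):
        self.values = _as_2d(self.values)
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        _check_nonnegative(self.values, "normalized matrix")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def zero_mask(self) -> np.ndarray:
        """Dense boolean mask, True where the (raw and normalized) entry is 0."""
        if sp.issparse(self.values):
            return ~(self.values != 0).toarray()
        return self.values == 0
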