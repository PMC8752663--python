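"""Cell/gene filtering and library normalization.

Normalization is the standard counts-per-``alpha`` log transform: each cell's
counts are scaled to a common total of ``alpha`` transcripts (default 10,000),
a pseudocount of 1 is added and the natural logarithm taken,

    x_ij = ln(1 + alpha * c_ij / sum_g c_ig).

Zeros map to zeros, so the sparsity pattern of the count matrix is preserved —
this is what later lets the pipeline distinguish "observed zero" from
"observed value" entries exactly.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ._exceptions import EmptyResultError, ZeroLibraryError
from .containers import CountMatrix, NormalizedMatrix

__all__ = ["filter_counts", "normalize"]


def _nonzero_per_row(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values != 0).sum(axis=1)).ravel()
    return np.count_nonzero(values, axis=1)


def _nonzero_per_col(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values != 0).sum(axis=0)).ravel()
    return np.count_nonzero(values, axis=0)


def filter_counts(
    counts: CountMatrix,
    min_genes_per_cell: int = 0,
    min_cells_per_gene: int = 0,
) -> CountMatrix:
    """Drop shallow cells, then rarely-detected genes.

    A cell is retained if it has *strictly more than* ``min_genes_per_cell``
    genes with non-zero counts; a gene is retained if (after the cell filter)
    it is non-zero in strictly more than ``min_cells_per_gene`` cells. The
    defaults (0, 0) keep everything with at least one non-zero entry only when
    a positive threshold is given — i.e. they are a no-op.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("filter thresholds must be non-negative")
    if min_genes_per_cell == 0 and min_cells_per_gene == 0:
        return counts

    cell_mask = _nonzero_per_row(counts.values) > min_genes_per_cell
    if not cell_mask.any():
        raise EmptyResultError(
            f"min_genes_per_cell={min_genes_per_cell} removed every cell"
        )
    values = counts.values[cell_mask]
    gene_mask = _nonzero_per_col(values) > min_cells_per_gene
    if not gene_mask.any():
        raise EmptyResultError(
            f"min_cells_per_gene={min_cells_per_gene} removed every gene"
        )
    values = values[:, gene_mask]
    return CountMatrix(
        values=values,
        cell_ids=[c for c, keep in zip(counts.cell_ids, cell_mask) if keep],
        gene_ids=[g for g, keep in zip(counts.gene_ids, gene_mask) if keep],
    )


def normalize(counts: CountMatrix, alpha: float = 10_000.0) -> NormalizedMatrix:
    """Library-normalize to ``alpha`` transcripts per cell and log-transform."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    values = counts.values
    if sp.issparse(values):
        libsize = np.asarray(values.sum(axis=1)).ravel().astype(float)
    else:
        libsize = values.sum(axis=1).astype(float)
    empty = libsize == 0
    if empty.any():
        offenders = [counts.cell_ids[i] for i in np.flatnonzero(empty)[:10]]
        raise ZeroLibraryError(
            f"{int(empty.sum())} cell(s) have zero total counts "
            f"(e.g. {offenders}); filter them before normalizing"
        )
    scale = alpha / libsize
    if sp.issparse(values):
        out = sp.diags(scale) @ values.tocsr().astype(float)
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(values * scale[:, None])
    return NormalizedMatrix(
        values=out,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
        alpha=float(alpha),
    )
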