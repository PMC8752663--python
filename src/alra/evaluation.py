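"""Zero-preservation / completion metrics, bulk-correlation classification,
and the Gini coefficient.

ZP (zero preservation) and TC (total zeros completed) depend only on zero
patterns: ZP is the fraction of entries in biological-zero genes that are
still zero after imputation, and TC is the fraction of all observed zeros
assigned a non-zero value. An ideal imputer has both high: it fills
technical zeros (high TC) without touching biological ones (high ZP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._exceptions import UndefinedStatisticError
from .containers import CountMatrix, NormalizedMatrix
from .simulation import (
    BulkProfiles,
    ProbabilityProfiles,
    SimulatedDataset,
    to_probabilities,
)

__all__ = [
    "ZeroMetrics",
    "zero_preservation_rate",
    "total_completion_rate",
    "sim_zero_metrics",
    "classify_by_bulk_correlation",
    "gini_coefficient",
]


def _dense(x) -> np.ndarray:
    if isinstance(x, (CountMatrix, NormalizedMatrix)):
        return x.to_dense()
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


@dataclass
class ZeroMetrics:
    """Zero-pattern metrics on a simulated dataset with known ground truth."""

    zp: float                 # fraction of biological zeros still zero
    tc: float                 # fraction of all observed zeros completed
    bio_preserved_pct: float  # 100 * zp
    tech_completed_pct: float # % of ground-truth technical zeros made non-zero


def zero_preservation_rate(before, after, bio_zero_genes, labels) -> float:
    """Zero entries in biological-zero genes after imputation, divided by zero
    entries in those genes before imputation.

    ``bio_zero_genes`` maps each cell-type label to the gene (column) indices
    that type does not express; ``labels`` gives each cell's type. Only
    entries (cell, gene) with the gene in the cell's type's set count.
    """
    b, a = _dense(before), _dense(after)
    if b.shape != a.shape:
        raise ValueError("matrix shapes differ")
    labels = np.asarray(labels)
    mask = np.zeros(b.shape, dtype=bool)
    for label, genes in bio_zero_genes.items():
        genes = np.asarray(list(genes), dtype=int)
        if genes.size and (genes.min() < 0 or genes.max() >= b.shape[1]):
            raise ValueError(f"gene index out of range for label {label!r}")
        rows = np.flatnonzero(labels == label)
        if rows.size and genes.size:
            mask[np.ix_(rows, genes)] = True
    denom = int(((b == 0) & mask).sum())
    if denom == 0:
        raise UndefinedStatisticError("no zero entries in biological-zero genes")
    numer = int(((a == 0) & mask).sum())
    return numer / denom


def total_completion_rate(before, after) -> float:
    """Fraction of entries zero before imputation that are non-zero after."""
    b, a = _dense(before), _dense(after)
    if b.shape != a.shape:
        raise ValueError("matrix shapes differ")
    zeros_before = b == 0
    n_before = int(zeros_before.sum())
    if n_before == 0:
        raise UndefinedStatisticError("no zeros before imputation")
    completed = int((zeros_before & (a != 0)).sum())
    return completed / n_before


def sim_zero_metrics(dataset: SimulatedDataset, imputed) -> ZeroMetrics:
    """ZP/TC and bio/tech percentages against simulation ground truth."""
    counts = dataset.counts.to_dense()
    a = _dense(imputed)
    if counts.shape != a.shape:
        raise ValueError("imputed matrix not aligned to dataset")
    bio = dataset.bio_zero_mask
    tech = (counts == 0) & ~bio
    if bio.sum() == 0:
        raise UndefinedStatisticError("dataset has no biological zeros")
    if tech.sum() == 0:
        raise UndefinedStatisticError("dataset has no technical zeros")
    zp = float((a[bio] == 0).mean())
    tech_completed = float((a[tech] != 0).mean())
    tc = total_completion_rate(counts, a)
    return ZeroMetrics(
        zp=zp,
        tc=tc,
        bio_preserved_pct=100.0 * zp,
        tech_completed_pct=100.0 * tech_completed,
    )


def _log_profile(v: np.ndarray, alpha: float) -> np.ndarray:
    total = v.sum()
    if total == 0:
        raise ValueError("profile with zero total")
    return np.log1p(alpha * v / total)


def classify_by_bulk_correlation(
    cells,
    bulk,
    labels=None,
    alpha: float = 10_000.0,
    cells_are_log: bool = False,
):
    """Assign each cell to the bulk profile it correlates best with.

    Both sides are placed on the same log scale (library-normalized to
    ``alpha`` and log1p-transformed); set ``cells_are_log=True`` when the
    cell matrix is already log-normalized (e.g. ALRA output). Ties go to the
    lowest sample index. Cells with constant expression have undefined
    correlation; they are assigned -1 and excluded from the misclassification
    rate, with a warning.

    Returns ``(assignments, misclassification_rate)``; the rate is None when
    no true labels are given.
    """
    c = _dense(cells).astype(float)
    if isinstance(bulk, BulkProfiles):
        bulk = to_probabilities(bulk)
    if isinstance(bulk, ProbabilityProfiles):
        profiles = bulk.p  # (S, m), rows sum to 1
    else:
        profiles = np.asarray(bulk, dtype=float)
    if profiles.shape[1] != c.shape[1]:
        raise ValueError("gene spaces not aligned")

    logp = np.vstack([_log_profile(row, alpha) for row in profiles])
    if cells_are_log:
        logc = c
    else:
        totals = c.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("a cell has zero total counts")
        logc = np.log1p(alpha * c / totals[:, None])

    logc_c = logc - logc.mean(axis=1, keepdims=True)
    logp_c = logp - logp.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(logc_c, axis=1)
    p_norm = np.linalg.norm(logp_c, axis=1)
    constant = c_norm == 0
    corr = np.zeros((c.shape[0], profiles.shape[0]))
    ok = ~constant
    corr[ok] = (logc_c[ok] @ logp_c.T) / np.outer(c_norm[ok], p_norm)
    assignments = np.argmax(corr, axis=1)  # argmax takes the lowest index on ties
    assignments[constant] = -1
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} cell(s) have constant expression; "
            "correlation undefined, excluded from the rate",
            stacklevel=2,
        )
    rate = None
    if labels is not None:
        labels = np.asarray(labels)
        valid = ~constant
        if valid.sum() == 0:
            raise UndefinedStatisticError("no cells with defined correlation")
        rate = float((assignments[valid] != labels[valid]).mean())
    return assignments, rate


def gini_coefficient(values) -> float:
    """Gini coefficient of a non-negative expression vector.

    Relative mean absolute difference with the population (n^2) denominator:
    ``sum_ij |v_i - v_j| / (2 n^2 mean)``. 0 iff all values are equal;
    scale-invariant.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise UndefinedStatisticError("empty vector")
    if np.any(v < 0):
        raise ValueError("Gini coefficient requires non-negative values")
    total = v.sum()
    if total == 0:
        raise UndefinedStatisticError("all-zero vector; Gini undefined")
    n = v.size
    v_sorted = np.sort(v)
    # Sorted identity: G = 2 * sum(i * v_(i)) / (n * sum(v)) - (n + 1) / n
    g = 2.0 * np.sum(np.arange(1, n + 1) * v_sorted) / (n * total) - (n + 1) / n
    return float(g)
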