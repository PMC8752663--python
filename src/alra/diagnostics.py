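"""Diagnostics: excess zeros, symmetry checks, and non-zero correlation.

The excess-zeros statistic estimates how many technical zeros remain
unimputed for a gene. If the low-rank values at observed-zero positions were
purely biological zeros they would be symmetric around 0, so the number of
positive values below the threshold would match the number of negative
values; any surplus of positives,

    psi_i = #{j : 0 < y_ij < tau_i and x_ij = 0}
          - #{j : y_ij < 0       and x_ij = 0},

counts sub-threshold technical zeros that were set back to zero because they
cannot be distinguished from biological zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._exceptions import UndefinedStatisticError
from .containers import NormalizedMatrix
from .core import ImputationResult, LowRankMatrix, ThresholdSet

__all__ = ["ExcessZeroReport", "excess_zeros", "zero_position_stats",
           "nonzero_correlation"]


@dataclass
class ExcessZeroReport:
    """Per-gene excess-zero counts."""

    psi: np.ndarray
    tau: np.ndarray
    n_pos_below: np.ndarray
    n_neg: np.ndarray
    gene_ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = self.gene_ids or [f"gene_{j}" for j in range(self.psi.size)]
        return pd.DataFrame(
            {
                "gene_id": ids,
                "psi": self.psi,
                "tau": self.tau,
                "n_pos_below": self.n_pos_below,
                "n_neg": self.n_neg,
            }
        )

    def extremes(self, n: int = 6) -> pd.DataFrame:
        """The n lowest- and n highest-psi genes, for inspection plots."""
        frame = self.to_frame().sort_values("psi", kind="stable")
        return pd.concat([frame.head(n), frame.tail(n)])


def _zero_mask(x) -> np.ndarray:
    if isinstance(x, NormalizedMatrix):
        return x.zero_mask()
    return np.asarray(x) == 0


def excess_zeros(x, lowrank, thresholds: ThresholdSet) -> ExcessZeroReport:
    """Count, per gene, positive sub-threshold and negative low-rank values at
    observed-zero positions; their difference is psi."""
    y = np.asarray(getattr(lowrank, "values", lowrank))
    mask0 = _zero_mask(x)
    if y.shape != mask0.shape:
        raise ValueError("matrix shapes differ")
    tau = thresholds.tau[None, :]
    n_pos_below = ((y > 0) & (y < tau) & mask0).sum(axis=0)
    n_neg = ((y < 0) & mask0).sum(axis=0)
    gene_ids = x.gene_ids if isinstance(x, NormalizedMatrix) else None
    return ExcessZeroReport(
        psi=n_pos_below - n_neg,
        tau=thresholds.tau,
        n_pos_below=n_pos_below,
        n_neg=n_neg,
        gene_ids=gene_ids,
    )


def zero_position_stats(
    lowrank,
    zero_mask: np.ndarray,
    min_positions: int = 200,
    quantiles=(0.001, 0.25, 0.5, 0.75, 0.999),
) -> pd.DataFrame:
    """Per-gene summary of the low-rank values at masked positions.

    Genes with fewer than ``min_positions`` masked entries are excluded
    (small-sample skewness is noise). Skewness is the adjusted Fisher-Pearson
    sample coefficient and is reported as NaN for genes with zero spread.
    """
    y = np.asarray(getattr(lowrank, "values", lowrank))
    zero_mask = np.asarray(zero_mask, dtype=bool)
    if y.shape != zero_mask.shape:
        raise ValueError("mask not aligned")
    rows = []
    counts = zero_mask.sum(axis=0)
    for j in np.flatnonzero(counts >= min_positions):
        vals = y[zero_mask[:, j], j]
        sd = float(np.std(vals, ddof=1))
        skew = float(scipy.stats.skew(vals, bias=False)) if sd > 0 else float("nan")
        row = {
            "gene_index": int(j),
            "n_positions": int(counts[j]),
            "mean": float(np.mean(vals)),
            "sd": sd,
            "skewness": skew,
        }
        for q in quantiles:
            row[f"q{q:g}"] = float(np.quantile(vals, q))
        rows.append(row)
    return pd.DataFrame(rows)


def nonzero_correlation(x, result) -> float:
    """Pearson correlation between observed (non-zero) normalized values and
    their imputed counterparts — a measure of how much ALRA denoised them."""
    imputed = result.imputed if isinstance(result, ImputationResult) else np.asarray(result)
    if isinstance(x, NormalizedMatrix):
        support = ~x.zero_mask()
        xd = x.to_dense()
    else:
        xd = np.asarray(x, dtype=float)
        support = xd != 0
    if support.sum() < 2:
        raise UndefinedStatisticError(
            "fewer than 2 non-zero entries; correlation undefined"
        )
    a, b = xd[support], imputed[support]
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("constant values; correlation undefined")
    return float(scipy.stats.pearsonr(a, b)[0])
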