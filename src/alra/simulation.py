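"""Multinomial scRNA-seq simulator with known biological zeros.

Each simulated cell is one multinomial draw: pick a cell type uniformly at
random among S bulk expression profiles, normalize the chosen profile's
counts to a probability vector p (so genes with zero bulk counts have
probability exactly 0), and draw N_l reads from Multinomial(N_l, p). Genes
with p = 0 in a cell's type are that cell's ground-truth biological zeros —
they can never receive a read — while expressed genes that receive no reads
are technical (sampling) zeros. Sequencing depth is controlled by scaling
the per-cell read counts N_l by a factor depth_scale in (0, 1].

Bulk profiles can be loaded from a gene x sample count table or generated
synthetically (:func:`synth_bulk`): gene-level log-normal base abundances
shared across samples, per-sample log-normal fold changes, and per-sample
biological-zero gene sets that partially overlap between samples — a
synthetic stand-in emulating related purified immune populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "BulkProfiles",
    "ProbabilityProfiles",
    "SimulatedDataset",
    "synth_bulk",
    "to_probabilities",
    "simulate_cells",
]


@dataclass
class BulkProfiles:
    """Bulk RNA-seq count profiles: ``counts[j, i]`` = reads of gene j in sample i."""

    counts: np.ndarray
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("bulk counts must be a genes x samples matrix")
        if np.any(self.counts < 0):
            raise ValueError("bulk counts must be non-negative")
        m, S = self.counts.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(S)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j:05d}" for j in range(m)]
        if len(self.sample_ids) != S or len(self.gene_ids) != m:
            raise ValueError("id lengths do not match matrix dimensions")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class ProbabilityProfiles:
    """Per-sample multinomial probabilities over genes: ``p[i]`` sums to 1."""

    p: np.ndarray
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        totals = self.p.sum(axis=1)
        if not np.allclose(totals, 1.0, atol=1e-12):
            raise ValueError("each probability vector must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.p.shape[0]

    @property
    def n_genes(self) -> int:
        return self.p.shape[1]


@dataclass
class SimulatedDataset:
    """Simulated single-cell counts with ground truth."""

    counts: CountMatrix
    labels: np.ndarray          # cell type index per cell, 0-based
    depths: np.ndarray          # realized per-cell totals round(depth_scale * N_l)
    depth_scale: float
    bio_zero_mask: np.ndarray   # True where the cell's type has p(gene) = 0
    sample_ids: list = field(default_factory=list)


def synth_bulk(
    S: int,
    m: int,
    zero_fraction: float = 0.3,
    overlap: float = 0.5,
    seed: int | None = None,
) -> BulkProfiles:
    """Generate ``S`` synthetic bulk profiles over ``m`` genes.

    Each sample has ``round(zero_fraction * m)`` biological-zero genes, a
    fraction ``overlap`` of which is shared by all samples (unexpressed
    everywhere) and the rest drawn per sample. Non-zero counts are long-tailed:
    gene base abundance ~ LogNormal(4, 1.5) shared across samples times a
    per-sample LogNormal(0, 0.5) fold change, rounded, floored at 1 read.
    """
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must be in [0, 1)")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    n_zero = int(round(zero_fraction * m))
    if n_zero >= m:
        raise ValueError("zero_fraction leaves no expressed genes")
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=4.0, sigma=1.5, size=m)
    counts = np.empty((m, S))
    n_shared = int(round(overlap * n_zero))
    shared = rng.choice(m, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(m), shared)
    for i in range(S):
        fold = rng.lognormal(mean=0.0, sigma=0.5, size=m)
        col = np.maximum(np.rint(base * fold), 1.0)
        private = rng.choice(rest, size=n_zero - n_shared, replace=False)
        col[shared] = 0.0
        col[private] = 0.0
        if col.sum() == 0:
            raise ValueError("a sample would be all-zero; lower zero_fraction")
        counts[:, i] = col
    return BulkProfiles(counts=counts.astype(np.int64))


def to_probabilities(bulk: BulkProfiles) -> ProbabilityProfiles:
    """Normalize each bulk sample to a multinomial probability vector."""
    totals = bulk.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("a bulk sample has zero total counts")
    p = (bulk.counts / totals).T  # (S, m)
    return ProbabilityProfiles(
        p=p, sample_ids=list(bulk.sample_ids), gene_ids=list(bulk.gene_ids)
    )


def _draw_depths(depths, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve the depth argument: explicit list, sampler spec, or default
    log-normal with median 2000 reads and log-sd 0.5."""
    if depths is None:
        depths = {"median": 2000.0, "sigma": 0.5}
    if isinstance(depths, dict):
        median = float(depths.get("median", 2000.0))
        sigma = float(depths.get("sigma", 0.5))
        return rng.lognormal(mean=np.log(median), sigma=sigma, size=n_cells)
    depths = np.asarray(depths, dtype=float)
    if depths.size != n_cells:
        raise ValueError(f"{depths.size} depths for {n_cells} cells")
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    return depths


def simulate_cells(
    profiles: ProbabilityProfiles,
    n_cells: int,
    depths=None,
    depth_scale: float = 1.0,
    seed: int | None = None,
    weights=None,
) -> SimulatedDataset:
    """Draw ``n_cells`` multinomial cells from the probability profiles.

    ``depths`` may be a list of per-cell read counts N_l, a dict
    ``{"median": ..., "sigma": ...}`` describing a log-normal sampler, or
    None for the default sampler. Each cell's total is exactly
    ``round(depth_scale * N_l)``. ``weights`` optionally biases the otherwise
    uniform cell-type assignment.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < depth_scale <= 1:
        raise ValueError("depth_scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    S, m = profiles.n_samples, profiles.n_genes
    labels = rng.choice(S, size=n_cells, p=weights)
    base_depths = _draw_depths(depths, n_cells, rng)
    totals = np.rint(depth_scale * base_depths).astype(np.int64)

    counts = np.zeros((n_cells, m), dtype=np.int64)
    for cell in range(n_cells):
        counts[cell] = rng.multinomial(totals[cell], profiles.p[labels[cell]])
    bio_zero_mask = profiles.p[labels] == 0

    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=[f"cell_{i:05d}" for i in range(n_cells)],
        gene_ids=list(profiles.gene_ids)
        if len(profiles.gene_ids) == m
        else [f"gene_{j:05d}" for j in range(m)],
    )
    return SimulatedDataset(
        counts=cm,
        labels=labels,
        depths=totals,
        depth_scale=float(depth_scale),
        bio_zero_mask=bio_zero_mask,
        sample_ids=list(profiles.sample_ids),
    )
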