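"""The adaptively thresholded low-rank approximation (ALRA) algorithm.

The pipeline, on a library-normalized log expression matrix X (cells x genes):

1. rank-k approximation Y = U_k S_k V_k' via randomized SVD (q = 10 extra
   power iterations for accuracy);
2. per-gene adaptive threshold tau_i = |quantile_p(Y[:, i])| with p = 0.001 —
   because the low-rank values at biological-zero positions are symmetrically
   distributed around 0, the magnitude of the (near-minimum) lower quantile
   bounds the positive values such positions can reach;
3. zero every entry with Y[i, j] < tau_j (strict), which removes all negative
   values and, with high probability, every biological zero;
4. rescale the surviving non-zero values of each gene affinely so their mean
   and standard deviation match those of the gene's non-zero values in X,
   clamping any value driven negative to 0;
5. restore every originally observed (non-zero in X) entry that ended up at 0
   back to its normalized value, so no observed value is destroyed.

The result is non-negative, its zero set is a subset of the observed zero
set, and every zero it imputes carries evidence of not being biological.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd
from sklearn.utils.validation import check_is_fitted

from ._exceptions import ValidationError
from .containers import CountMatrix, NormalizedMatrix
from .preprocess import normalize
from .rank import RankEstimate, estimate_rank, leading_singular_values

__all__ = [
    "LowRankMatrix",
    "ThresholdSet",
    "ImputationResult",
    "lowrank_approximate",
    "compute_thresholds",
    "apply_thresholds",
    "rescale_genes",
    "restore_observed",
    "ALRA",
    "alra",
]


@dataclass
class LowRankMatrix:
    """Dense rank-k reconstruction plus its factors."""

    values: np.ndarray
    k: int
    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray
    q_power_iterations: int = 10
    seed: int | None = None

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ThresholdSet:
    """Per-gene adaptive thresholds tau_i = |quantile_p of the gene's low-rank values|."""

    tau: np.ndarray
    p_quantile: float = 0.001

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if not 0 < self.p_quantile < 0.5:
            raise ValidationError("p_quantile must be in (0, 0.5)")
        if np.any(self.tau < 0):
            raise ValidationError("thresholds must be non-negative")


@dataclass
class ImputationResult:
    """Output of the full pipeline with provenance."""

    imputed: np.ndarray
    lowrank: LowRankMatrix
    thresholds: ThresholdSet
    rank_estimate: RankEstimate | None
    restored_mask: np.ndarray
    rescale_applied: bool
    cell_ids: list | None = None
    gene_ids: list | None = None

    @property
    def shape(self):
        return self.imputed.shape


def _dense(x) -> np.ndarray:
    if isinstance(x, NormalizedMatrix):
        return x.to_dense()
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x, dtype=float)


def lowrank_approximate(
    x,
    k: int,
    q: int = 10,
    seed: int | None = None,
    method: str = "randomized",
) -> LowRankMatrix:
    """Best rank-``k`` approximation of the normalized matrix.

    ``method="randomized"`` uses a randomized range finder with ``q`` extra
    power iterations; ``method="exact"`` computes a full SVD and truncates
    (the small-matrix oracle path).
    """
    m = x.values if isinstance(x, NormalizedMatrix) else x
    if not 1 <= k <= min(m.shape):
        raise ValueError(f"k={k} outside [1, {min(m.shape)}]")
    if method == "exact":
        u, s, vt = np.linalg.svd(_dense(m), full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    elif method == "randomized":
        u, s, vt = randomized_svd(
            m if sp.issparse(m) else np.asarray(m, dtype=float),
            n_components=k,
            n_iter=q,
            power_iteration_normalizer="QR",
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown SVD method {method!r}")
    values = (u * s) @ vt
    # A column of x that is entirely zero is orthogonal to every singular
    # vector with a non-zero singular value, so its reconstruction is exactly
    # zero in exact arithmetic; enforce that against floating-point noise.
    if sp.issparse(m):
        detected = np.asarray((m != 0).sum(axis=0)).ravel() > 0
    else:
        detected = np.count_nonzero(np.asarray(m), axis=0) > 0
    values[:, ~detected] = 0.0
    return LowRankMatrix(values=values, k=k, u=u, s=s, vt=vt,
                         q_power_iterations=q, seed=seed)


def compute_thresholds(lowrank, p: float = 0.001) -> ThresholdSet:
    """Per-gene threshold: magnitude of the gene's ``p`` quantile over cells.

    The quantile uses linear interpolation between order statistics (quantile
    0 = minimum), so for p = 0.001 and fewer than ~1000 cells this is
    effectively the magnitude of the gene's most negative low-rank value.
    """
    y = np.asarray(getattr(lowrank, "values", lowrank))
    if y.shape[0] < 2:
        raise ValueError("need at least 2 cells to take a quantile")
    tau = np.abs(np.quantile(y, p, axis=0, method="linear"))
    return ThresholdSet(tau=tau, p_quantile=p)


def apply_thresholds(lowrank, thresholds: ThresholdSet) -> np.ndarray:
    """Zero every entry strictly below its gene's threshold.

    tau_i >= 0, so all negative low-rank values are removed; entries equal to
    tau_i survive.
    """
    y = np.asarray(getattr(lowrank, "values", lowrank))
    tau = thresholds.tau
    if tau.size != y.shape[1]:
        raise ValueError("thresholds not aligned to genes")
    out = np.where(y < tau[None, :], 0.0, y)
    return out


def _nonzero_moments_sparse(m: sp.spmatrix):
    """Per-column count, mean and sample sd of the non-zero entries."""
    csc = m.tocsc()
    n = np.diff(csc.indptr).astype(float)
    total = np.asarray(csc.sum(axis=0)).ravel()
    totalsq = np.asarray(csc.multiply(csc).sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
        var = (totalsq - n * mean**2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0, None))
    return n, mean, sd


def _nonzero_moments_dense(m: np.ndarray):
    nz = m != 0
    n = nz.sum(axis=0).astype(float)
    total = m.sum(axis=0)
    totalsq = (m**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
        var = (totalsq - n * mean**2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0, None))
    return n, mean, sd


def rescale_genes(thresholded: np.ndarray, x, return_info: bool = False):
    """Affinely map each gene's non-zero values to match the non-zero mean
    and sample standard deviation of the normalized matrix for that gene.

    Genes with fewer than 2 non-zero entries on either side, or with zero
    spread on either side, are left unscaled. Mapped values that fall below 0
    are clamped to exactly 0.

    With ``return_info=True`` also returns a dict holding the per-gene affine
    parameters and masks (used by the estimator's out-of-sample path and the
    diagnostics).
    """
    t = np.asarray(thresholded, dtype=float)
    xm = x.values if isinstance(x, NormalizedMatrix) else x
    if t.shape != xm.shape:
        raise ValueError("matrix shapes differ")
    if sp.issparse(xm):
        n_x, mean_x, sd_x = _nonzero_moments_sparse(xm)
    else:
        n_x, mean_x, sd_x = _nonzero_moments_dense(np.asarray(xm, dtype=float))
    n_t, mean_t, sd_t = _nonzero_moments_dense(t)

    eligible = (n_t >= 2) & (n_x >= 2) & (sd_t > 0) & (sd_x > 0)
    scale = np.ones_like(sd_x)
    shift = np.zeros_like(mean_x)
    scale[eligible] = sd_x[eligible] / sd_t[eligible]
    shift[eligible] = mean_x[eligible] - scale[eligible] * mean_t[eligible]

    out = t.copy()
    nz = t != 0
    cols = np.broadcast_to(eligible, t.shape) & nz
    out[cols] = t[cols] * np.broadcast_to(scale, t.shape)[cols] + np.broadcast_to(
        shift, t.shape
    )[cols]
    clamped = out < 0
    out[clamped] = 0.0
    if return_info:
        info = {
            "scaled": eligible,
            "scale": scale,
            "shift": shift,
            "clamped": clamped,
            "n_clamped_per_gene": clamped.sum(axis=0),
        }
        return out, info
    return out


def restore_observed(rescaled: np.ndarray, x):
    """Set every entry that is 0 after thresholding/rescaling but was observed
    non-zero back to its normalized value.

    Returns ``(restored, restored_mask)``; the mask flags the entries reset.
    """
    r = np.asarray(rescaled, dtype=float)
    xd = _dense(x)
    if r.shape != xd.shape:
        raise ValueError("matrix shapes differ")
    mask = (r == 0) & (xd > 0)
    out = r.copy()
    out[mask] = xd[mask]
    return out, mask


class ALRA(TransformerMixin, BaseEstimator):
    """Zero-preserving imputation of scRNA-seq counts by adaptively
    thresholded low-rank approximation.

    Parameters
    ----------
    k : int or None
        Rank of the approximation. ``None`` (default) selects it from the
        spacings of the leading singular values.
    alpha : float
        Library-normalization target (transcripts per cell) applied before
        the log transform when the input is raw counts.
    quantile_p : float
        Quantile level p of the per-gene adaptive threshold.
    n_singular_values : int
        Number of leading singular values used for rank selection (the rank
        is assumed to be below this).
    q_rank, q_svd : int
        Extra power iterations for the rank-selection spectrum (cheap, q = 2)
        and for the rank-k approximation itself (accurate, q = 10).
    noise_start : int
        1-based index of the first singular-value spacing of the noise window.
    rescale, restore : bool
        Enable the per-gene moment-matching rescale and the restoration of
        observed values, respectively.
    assume_normalized : bool
        If True, ``X`` is already a log-normalized matrix and the
        normalization step is skipped.
    svd_method : {"randomized", "exact"}
        SVD backend for the rank-k approximation.
    random_state : int or None
        Seed for the randomized SVD; fixed seeds give bit-reproducible runs.

    Attributes
    ----------
    rank_ : int
        Rank actually used.
    rank_estimate_ : RankEstimate or None
        Spacing statistics when the rank was selected automatically.
    thresholds_ : ThresholdSet
        Per-gene adaptive thresholds.
    result_ : ImputationResult
        Full output of the fitted (training) matrix, including the restored
        mask and the factors of the low-rank approximation.

    Notes
    -----
    The algorithm is transductive: ``fit_transform(X)`` is the canonical way
    to impute a matrix. ``transform`` on new data projects it onto the fitted
    right singular subspace and applies the fitted thresholds and per-gene
    affine maps — an out-of-sample approximation that coincides with the
    in-sample result up to the accuracy of the randomized SVD.
    """

    def __init__(
        self,
        k: int | None = None,
        alpha: float = 10_000.0,
        quantile_p: float = 0.001,
        n_singular_values: int = 100,
        q_rank: int = 2,
        q_svd: int = 10,
        noise_start: int = 80,
        rescale: bool = True,
        restore: bool = True,
        assume_normalized: bool = False,
        svd_method: str = "randomized",
        random_state: int | None = None,
    ):
        self.k = k
        self.alpha = alpha
        self.quantile_p = quantile_p
        self.n_singular_values = n_singular_values
        self.q_rank = q_rank
        self.q_svd = q_svd
        self.noise_start = noise_start
        self.rescale = rescale
        self.restore = restore
        self.assume_normalized = assume_normalized
        self.svd_method = svd_method
        self.random_state = random_state

    def _normalize_input(self, X) -> NormalizedMatrix:
        if isinstance(X, NormalizedMatrix):
            return X
        if isinstance(X, CountMatrix):
            if self.assume_normalized:
                return NormalizedMatrix(
                    values=X.values, cell_ids=X.cell_ids, gene_ids=X.gene_ids,
                    alpha=self.alpha,
                )
            return normalize(X, alpha=self.alpha)
        if self.assume_normalized:
            m = X.tocsr() if sp.issparse(X) else np.asarray(X, dtype=float)
            n, g = m.shape
            return NormalizedMatrix(values=m, cell_ids=[f"cell_{i}" for i in range(n)],
                                    gene_ids=[f"gene_{j}" for j in range(g)],
                                    alpha=self.alpha)
        return normalize(CountMatrix(values=X), alpha=self.alpha)

    def fit(self, X, y=None):
        """Run the pipeline on ``X``; the imputed training matrix is kept in
        ``result_``."""
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        xn = self._normalize_input(X)
        self.n_features_in_ = xn.n_genes

        if self.k is not None:
            if not 1 <= self.k <= min(xn.shape):
                raise ValueError(f"k={self.k} outside [1, {min(xn.shape)}]")
            k, self.rank_estimate_ = int(self.k), None
        else:
            spectrum = leading_singular_values(
                xn, n_values=self.n_singular_values, q=self.q_rank,
                seed=self.random_state,
            )
            self.rank_estimate_ = estimate_rank(spectrum, noise_start=self.noise_start)
            self.singular_spectrum_ = spectrum
            k = self.rank_estimate_.k
        self.rank_ = k

        lowrank = lowrank_approximate(
            xn, k=k, q=self.q_svd, seed=self.random_state, method=self.svd_method
        )
        thresholds = compute_thresholds(lowrank, p=self.quantile_p)
        t = apply_thresholds(lowrank, thresholds)

        if self.rescale:
            rescaled, info = rescale_genes(t, xn, return_info=True)
        else:
            rescaled = t
            info = {
                "scaled": np.zeros(xn.n_genes, dtype=bool),
                "scale": np.ones(xn.n_genes),
                "shift": np.zeros(xn.n_genes),
                "clamped": np.zeros_like(t, dtype=bool),
                "n_clamped_per_gene": np.zeros(xn.n_genes, dtype=int),
            }

        if self.restore:
            imputed, restored_mask = restore_observed(rescaled, xn)
        else:
            imputed, restored_mask = rescaled, np.zeros_like(rescaled, dtype=bool)

        if sp.issparse(xn.values):
            self.detected_genes_ = np.asarray((xn.values != 0).sum(axis=0)).ravel() > 0
        else:
            self.detected_genes_ = np.count_nonzero(xn.values, axis=0) > 0
        self.normalized_ = xn
        self.lowrank_ = lowrank
        self.thresholds_ = thresholds
        self.components_ = lowrank.vt
        self.singular_values_ = lowrank.s
        self.rescale_info_ = info
        self.result_ = ImputationResult(
            imputed=imputed,
            lowrank=lowrank,
            thresholds=thresholds,
            rank_estimate=self.rank_estimate_,
            restored_mask=restored_mask,
            rescale_applied=bool(self.rescale),
            cell_ids=list(xn.cell_ids),
            gene_ids=list(xn.gene_ids),
        )
        return imputed

    def transform(self, X) -> np.ndarray:
        """Impute ``X`` with the fitted subspace, thresholds and gene maps."""
        check_is_fitted(self, "result_")
        xn = self._normalize_input(X)
        if xn.n_genes != self.n_features_in_:
            raise ValueError(
                f"X has {xn.n_genes} genes; fitted on {self.n_features_in_}"
            )
        vt = self.components_
        m = xn.values
        y = (m @ vt.T) @ vt
        y = np.asarray(y)
        y[:, ~self.detected_genes_] = 0.0
        t = np.where(y < self.thresholds_.tau[None, :], 0.0, y)
        if self.rescale:
            info = self.rescale_info_
            cols = np.broadcast_to(info["scaled"], t.shape) & (t != 0)
            t = t.copy()
            t[cols] = (
                t[cols] * np.broadcast_to(info["scale"], t.shape)[cols]
                + np.broadcast_to(info["shift"], t.shape)[cols]
            )
            t[t < 0] = 0.0
        if self.restore:
            t, _ = restore_observed(t, xn)
        return t


def alra(
    counts_or_normalized,
    *,
    alpha: float = 10_000.0,
    p: float = 0.001,
    k: int | None = None,
    q_rank: int = 2,
    q_svd: int = 10,
    noise_start: int = 80,
    seed: int | None = None,
    rescale: bool = True,
    restore: bool = True,
    svd_method: str = "randomized",
) -> ImputationResult:
    """Run the full pipeline and return the :class:`ImputationResult`.

    Accepts a :class:`~alra.containers.CountMatrix` (normalized internally
    with ``alpha``), a :class:`~alra.containers.NormalizedMatrix`, or a plain
    array/sparse matrix of raw counts.
    """
    est = ALRA(
        k=k,
        alpha=alpha,
        quantile_p=p,
        q_rank=q_rank,
        q_svd=q_svd,
        noise_start=noise_start,
        rescale=rescale,
        restore=restore,
        svd_method=svd_method,
        random_state=seed,
    )
    est.fit_transform(counts_or_normalized)
    return est.result_
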