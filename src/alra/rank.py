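"""Rank selection from the spacings of consecutive singular values.

Noise in an expression matrix manifests as a long, slowly decaying tail of
singular values, while signal (distinct cell populations, gene modules)
produces a few large, well-separated leading values. The rank is chosen from
the non-negative spacings of the descending spectrum,

    d_j = sigma_j - sigma_{j+1},    j = 1, ..., K - 1,

by comparing each spacing with the typical spacing deep in the noise tail:
with mu and sd the mean and sample standard deviation of a trailing "noise
window" of spacings, the selected rank is

    k = max{ j : d_j > mu + 6 * sd },

i.e. the last spacing that is significantly larger than noise spacings. For
the default 100-value spectrum the noise window is d_80 .. d_99.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from ._exceptions import NoSignalError
from .containers import NormalizedMatrix

__all__ = [
    "SingularSpectrum",
    "RankEstimate",
    "leading_singular_values",
    "estimate_rank",
    "spacing_table",
]


@dataclass
class SingularSpectrum:
    """Leading singular values of a matrix, in descending order."""

    sigma: np.ndarray
    q_power_iterations: int = 2
    seed: int | None = None

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 1 or self.sigma.size < 2:
            raise ValueError("spectrum must be a 1-d array of >= 2 values")
        if np.any(np.diff(self.sigma) > 1e-9 * max(self.sigma[0], 1.0)):
            raise ValueError("singular values must be in descending order")

    def __len__(self) -> int:
        return self.sigma.size


@dataclass
class RankEstimate:
    """A selected rank together with the spacing statistics behind it."""

    k: int
    spacings: np.ndarray
    mu_noise: float
    sd_noise: float
    noise_window: tuple = (80, 99)  # 1-based first/last spacing index used
    threshold: float = 0.0
    statistic: float = field(default=float("nan"))  # d_k itself

    def __post_init__(self):
        self.spacings = np.asarray(self.spacings, dtype=float)


def _matrix_of(x) -> object:
    return x.values if isinstance(x, NormalizedMatrix) else x


def leading_singular_values(
    x,
    n_values: int = 100,
    q: int = 2,
    seed: int | None = None,
) -> SingularSpectrum:
    """Top ``n_values`` singular values via randomized SVD with ``q`` extra
    power iterations.

    ``n_values`` larger than ``min(shape) - 1`` is reduced automatically
    (with a warning) so the trailing noise window still exists.
    """
    m = _matrix_of(x)
    min_dim = min(m.shape)
    if n_values > min_dim:
        warnings.warn(
            f"n_values={n_values} exceeds min(shape)={min_dim}; "
            f"reduced to {min_dim - 1}",
            stacklevel=2,
        )
        n_values = min_dim - 1
    if n_values < 2:
        raise ValueError("need at least 2 singular values")
    _, s, _ = randomized_svd(
        m if sp.issparse(m) else np.asarray(m, dtype=float),
        n_components=n_values,
        n_iter=q,
        power_iteration_normalizer="QR",
        random_state=seed,
    )
    return SingularSpectrum(sigma=np.sort(s)[::-1], q_power_iterations=q, seed=seed)


def estimate_rank(
    spectrum: SingularSpectrum,
    noise_start: int = 80,
    n_sd: float = 6.0,
) -> RankEstimate:
    """Select the rank as the last spacing exceeding ``mu + n_sd * sd`` of
    the noise-window spacings.

    For a spectrum of K values there are K - 1 spacings; the noise window is
    ``d_{noise_start} .. d_{K-1}`` (1-based) when the spectrum is long enough,
    otherwise the last 20% of spacings (at least 5). Comparison is strict, so
    a perfectly flat spectrum (sd = 0, every spacing equal to mu) yields no
    rank rather than a spurious one.
    """
    sigma = np.asarray(spectrum.sigma, dtype=float)
    K = sigma.size
    spacings = sigma[:-1] - sigma[1:]  # d_j = sigma_j - sigma_{j+1}, j = 1..K-1
    n_spacings = spacings.size
    if n_spacings < 5:
        raise ValueError("spectrum too short to estimate a noise level")
    if n_spacings >= noise_start + 1:
        start = noise_start - 1  # 0-based index of d_{noise_start}
    else:
        start = n_spacings - max(5, int(np.ceil(0.2 * n_spacings)))
    window = spacings[start:]
    mu = float(np.mean(window))
    sd = float(np.std(window, ddof=1))
    threshold = mu + n_sd * sd
    above = np.flatnonzero(spacings > threshold)
    if above.size == 0:
        raise NoSignalError(
            "no singular-value spacing exceeds the noise threshold "
            f"(mu={mu:.4g}, sd={sd:.4g}); the spectrum has no detectable "
            "signal component — pass the rank k explicitly"
        )
    k = int(above[-1] + 1)  # 1-based spacing index == number of components kept
    return RankEstimate(
        k=k,
        spacings=spacings,
        mu_noise=mu,
        sd_noise=sd,
        noise_window=(start + 1, n_spacings),
        threshold=threshold,
        statistic=float(spacings[k - 1]),
    )


def spacing_table(spectrum: SingularSpectrum) -> pd.DataFrame:
    """Per-component table (j, sigma_j, d_j) for spacing-curve plots."""
    sigma = np.asarray(spectrum.sigma, dtype=float)
    d = np.append(sigma[:-1] - sigma[1:], np.nan)
    return pd.DataFrame(
        {"j": np.arange(1, sigma.size + 1), "sigma": sigma, "spacing": d}
    )
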