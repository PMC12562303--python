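"""The ordinal spectrum: Fourier transform of the rank autocovariance.

Because the rank autocovariance of a stationary coded sequence is even in the
lag, the two-sided transform

    OS(f) = sum_{m=-(N-1)}^{N-1} Cov(m) exp(-i 2 pi f m)

collapses to the cosine series

    OS(f) = Cov(0) + 2 * sum_{m=1}^{N-1} Cov(m) cos(2 pi f m),

which is evaluated directly (no taper by default) on a uniform grid of
normalized frequencies in [0, 0.5] cycles/sample.  The output is exactly real
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ParameterError
from .rank_dynamics import RankAutocovariance, rank_autocovariance
from .symbolizer import SymbolSequence

__all__ = [
    "OrdinalSpectrum",
    "frequency_grid",
    "ordinal_spectrum",
    "shuffled_symbol_spectrum",
]

DEFAULT_N_FREQ = 256


@dataclass(frozen=True)
class OrdinalSpectrum:
    """OS(f) sampled on a strictly increasing grid in [0, 0.5]."""

    frequencies: np.ndarray
    values: np.ndarray
    max_lag: int
    metadata: dict = field(default_factory=dict, repr=False)

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.frequencies, self.values]),
            fmt="%.17g",
            delimiter="\t",
            header="normalized_frequency\tOS",
            comments="",
        )


def frequency_grid(n_freq: int = DEFAULT_N_FREQ) -> np.ndarray:
    """Uniform normalized-frequency grid f_k = k / (2 (n_freq - 1)),
    k = 0..n_freq-1, spanning [0, 0.5] cycles/sample."""
    n_freq = int(n_freq)
    if n_freq < 2:
        raise ParameterError("n_freq must be >= 2")
    return np.arange(n_freq) / (2.0 * (n_freq - 1))


def _cosine_matrix(freqs: np.ndarray, n_lags: int) -> np.ndarray:
    m = np.arange(1, n_lags)
    return np.cos(2.0 * np.pi * np.outer(freqs, m))


def ordinal_spectrum(cov: RankAutocovariance, n_freq: int = DEFAULT_N_FREQ,
                     taper: str | None = None,
                     _cos: np.ndarray | None = None) -> OrdinalSpectrum:
    """Evaluate OS(f) from a rank autocovariance by direct cosine summation.

    Parameters
    ----------
    cov : RankAutocovariance
    n_freq : number of grid points on [0, 0.5]
    taper : None or "bartlett"
        Optional triangular lag window for variance reduction; off by
        default so OS(f) is the plain transform of Cov(m).
    _cos : precomputed cosine matrix (internal fast path for ensembles);
        must match ``frequency_grid(n_freq)`` and ``cov.max_lag``.
    """
    c = np.asarray(cov.cov, dtype=float)
    if not np.all(np.isfinite(c)):
        raise InvalidInputError("non-finite autocovariance")
    N = c.size
    if taper == "bartlett" and N > 1:
        c = c * (1.0 - np.arange(N) / N)
    elif taper not in (None, "bartlett"):
        raise ParameterError(f"unknown taper {taper!r}")
    freqs = frequency_grid(n_freq)
    if N == 1:
        values = np.full(freqs.size, c[0])
    else:
        cos = _cos if _cos is not None else _cosine_matrix(freqs, N)
        values = c[0] + 2.0 * (cos @ c[1:])
    return OrdinalSpectrum(
        frequencies=freqs,
        values=values,
        max_lag=N,
        metadata={"taper": taper, "method": cov.method,
                  "normalization": cov.normalization},
    )


def shuffled_symbol_spectrum(seq: SymbolSequence, n_shuffles: int = 200,
                             seed=None, max_lag: int | None = None,
                             n_freq: int = DEFAULT_N_FREQ,
                             cov_method: str = "markov",
                             normalization: str = "biased"):
    """Mean ordinal spectrum (and 5th-95th percentile envelope) over random
    permutations of the symbol codes.

    Shuffling destroys all temporal structure of the symbolic sequence while
    keeping the pattern histogram, so the mean spectrum is flat at Var(S)
    regardless of the original dynamics — a reference against which genuine
    spectral structure can be judged, but one that cannot separate chaos from
    linearly correlated noise.
    """
    n_shuffles = int(n_shuffles)
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = frequency_grid(n_freq)
    spectra = np.empty((n_shuffles, freqs.size))
    cos = None
    n_lags = 1
    for k in range(n_shuffles):
        shuffled = SymbolSequence(
            codes=rng.permutation(seq.codes), params=seq.params
        )
        cov = rank_autocovariance(shuffled, max_lag=max_lag,
                                  method=cov_method,
                                  normalization=normalization)
        n_lags = cov.max_lag
        if cos is None and n_lags > 1:
            cos = _cosine_matrix(freqs, n_lags)
        spectra[k] = ordinal_spectrum(cov, n_freq=n_freq, _cos=cos).values
    mean = spectra.mean(axis=0)
    lo, hi = np.percentile(spectra, [5, 95], axis=0)
    return (
        OrdinalSpectrum(frequencies=freqs, values=mean, max_lag=n_lags,
                        metadata={"kind": "shuffled_mean",
                                  "n_shuffles": n_shuffles}),
        lo,
        hi,
    )
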