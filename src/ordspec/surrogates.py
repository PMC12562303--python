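"""IAAFT surrogates and the per-frequency significance test.

The null hypothesis is that the observed series is a (possibly monotone
static transform of a) linearly correlated Gaussian process.  IAAFT
surrogates preserve the amplitude distribution exactly and the power spectrum
to convergence while scrambling all higher-order temporal structure.  Each
surrogate is pushed through the identical symbolize -> rank autocovariance ->
ordinal spectrum pipeline; the original spectrum is compared to the surrogate
ensemble frequency-by-frequency with a z-test, and Benjamini-Hochberg FDR
controls the multiplicity over the frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateEnsembleError, InvalidInputError, ParameterError
from .rank_dynamics import rank_autocovariance
from .spectrum import (
    DEFAULT_N_FREQ,
    OrdinalSpectrum,
    _cosine_matrix,
    frequency_grid,
    ordinal_spectrum,
)
from .symbolizer import EmbeddingParams, as_values, symbolize

__all__ = [
    "SurrogateEnsemble",
    "SignificanceReport",
    "iaaft",
    "build_ensemble",
    "significance",
]

DEFAULT_N_SURROGATES = 500
IAAFT_MAX_ITER = 100


def iaaft(series, max_iter: int = IAAFT_MAX_ITER, seed=None) -> np.ndarray:
    """One iterative amplitude-adjusted Fourier-transform surrogate.

    Alternates a spectrum step (impose the original Fourier amplitudes,
    keeping current phases) with an amplitude step (rank-remap onto the
    sorted original values) until the rank ordering reaches a fixed point or
    ``max_iter`` is hit.  The loop ends on the amplitude step, so the
    surrogate's value multiset equals the original's exactly.
    """
    x = as_values(series)
    if x.size < 8:
        raise InvalidInputError("series too short for IAAFT (need T >= 8)")
    if int(max_iter) < 1:
        raise ParameterError("max_iter must be >= 1")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IAAFT surrogate equals the original",
                      UserWarning, stacklevel=2)
        return x.copy()
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    y = rng.permutation(x)
    prev_order = None
    for _ in range(int(max_iter)):
        spec = np.fft.rfft(y)
        amp = np.abs(spec)
        phases = np.where(amp > 0, spec / np.where(amp > 0, amp, 1.0), 1.0)
        y = np.fft.irfft(target_amp * phases, n=x.size)
        order = np.argsort(np.argsort(y, kind="stable"), kind="stable")
        y = sorted_x[order]
        if prev_order is not None and np.array_equal(order, prev_order):
            break
        prev_order = order
    return y


def iaaft_many(series, seeds, max_iter: int = IAAFT_MAX_ITER) -> np.ndarray:
    """Batch of IAAFT surrogates, one per seed, as an ``(n, T)`` array.

    Row ``k`` is bit-identical to ``iaaft(series, max_iter, seeds[k])``; the
    rows are iterated together (batched FFTs and argsorts) and frozen
    individually as each reaches its rank fixed point.
    """
    x = as_values(series)
    if x.size < 8:
        raise InvalidInputError("series too short for IAAFT (need T >= 8)")
    if int(max_iter) < 1:
        raise ParameterError("max_iter must be >= 1")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IAAFT surrogates equal the original",
                      UserWarning, stacklevel=2)
        return np.tile(x, (len(seeds), 1))
    n = len(seeds)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    y = np.stack([np.random.default_rng(s).permutation(x) for s in seeds])
    prev_order = np.full((n, x.size), -1, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for _ in range(int(max_iter)):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        spec = np.fft.rfft(y[idx], axis=1)
        amp = np.abs(spec)
        phases = np.where(amp > 0, spec / np.where(amp > 0, amp, 1.0), 1.0)
        z = np.fft.irfft(target_amp[None, :] * phases, n=x.size, axis=1)
        order = np.argsort(np.argsort(z, axis=1, kind="stable"),
                           axis=1, kind="stable")
        y[idx] = sorted_x[order]
        converged = np.all(order == prev_order[idx], axis=1)
        prev_order[idx] = order
        active[idx[converged]] = False
    return y


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Ordinal spectra of an IAAFT surrogate ensemble on a shared grid."""

    frequencies: np.ndarray
    spectra: np.ndarray = field(repr=False)       # (n_surrogates, n_freq)
    mean: np.ndarray = field(repr=False)
    std: np.ndarray = field(repr=False)
    percentile_lo: np.ndarray = field(repr=False)  # 5th
    percentile_hi: np.ndarray = field(repr=False)  # 95th

    @property
    def n_surrogates(self) -> int:
        return self.spectra.shape[0]


def build_ensemble(series, params: EmbeddingParams,
                   n_surrogates: int = DEFAULT_N_SURROGATES, seed=None,
                   max_lag: int | None = None, n_freq: int = DEFAULT_N_FREQ,
                   cov_method: str = "markov", normalization: str = "biased",
                   tie_rule: str = "stable",
                   max_iter: int = IAAFT_MAX_ITER) -> SurrogateEnsemble:
    """Ordinal spectra of ``n_surrogates`` IAAFT surrogates, each processed
    with the same embedding, lag range and estimator options as the data."""
    if int(n_surrogates) < 2:
        raise ParameterError("n_surrogates must be >= 2")
    x = as_values(series)
    rng = np.random.default_rng(seed)
    children = [int(rng.integers(0, 2**31 - 1))
                for _ in range(int(n_surrogates))]
    surrogate_rows = iaaft_many(x, children, max_iter=max_iter)
    freqs = frequency_grid(n_freq)
    spectra = []
    failures = 0
    cos = None
    for k, child in enumerate(children):
        try:
            seq = symbolize(surrogate_rows[k], params, tie_rule=tie_rule,
                            seed=child)
            cov = rank_autocovariance(seq, max_lag=max_lag,
                                      method=cov_method,
                                      normalization=normalization)
            if cos is None and cov.max_lag > 1:
                cos = _cosine_matrix(freqs, cov.max_lag)
            spectra.append(ordinal_spectrum(cov, n_freq=n_freq,
                                            _cos=cos).values)
        except Exception as exc:  # noqa: BLE001 - per-surrogate isolation
            failures += 1
            if failures > 0.1 * int(n_surrogates):
                raise RuntimeError(
                    f"more than 10% of surrogates failed (last: {exc})"
                ) from exc
    spectra = np.asarray(spectra)
    std = spectra.std(axis=0, ddof=1)
    lo, hi = np.percentile(spectra, [5, 95], axis=0)
    return SurrogateEnsemble(
        frequencies=freqs,
        spectra=spectra,
        mean=spectra.mean(axis=0),
        std=std,
        percentile_lo=lo,
        percentile_hi=hi,
    )


@dataclass(frozen=True)
class SignificanceReport:
    """Per-frequency test of the ordinal spectrum against the surrogate null."""

    frequencies: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    bands: tuple
    alpha: float
    verdict: str  # "null_rejected" | "null_not_rejected"

    @property
    def rejected(self) -> bool:
        return self.verdict == "null_rejected"

    @property
    def min_q(self) -> float:
        return float(self.q.min())


def _contiguous_bands(freqs: np.ndarray, mask: np.ndarray) -> tuple:
    bands = []
    in_band = False
    start = 0
    for k, flag in enumerate(mask):
        if flag and not in_band:
            in_band, start = True, k
        elif not flag and in_band:
            bands.append((float(freqs[start]), float(freqs[k - 1])))
            in_band = False
    if in_band:
        bands.append((float(freqs[start]), float(freqs[-1])))
    return tuple(bands)


def significance(os: OrdinalSpectrum, ens: SurrogateEnsemble,
                 alpha: float = 0.05,
                 pvalue_method: str = "normal") -> SignificanceReport:
    """Two-sided per-frequency test with Benjamini-Hochberg FDR correction.

    ``pvalue_method="normal"`` converts z-scores through the standard normal;
    ``"percentile"`` uses the surrogate ensemble's empirical rank instead,
    which is robust when the surrogate spectra are visibly non-Gaussian.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if os.frequencies.shape != ens.frequencies.shape or not np.allclose(
        os.frequencies, ens.frequencies
    ):
        raise ParameterError("spectrum and ensemble use different grids")
    if np.any(ens.std == 0):
        raise DegenerateEnsembleError(
            "surrogate ensemble has zero spread at some frequency; "
            "z-test undefined"
        )
    z = (os.values - ens.mean) / ens.std
    if pvalue_method == "normal":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif pvalue_method == "percentile":
        n = ens.n_surrogates
        above = (ens.spectra >= os.values[None, :]).sum(axis=0)
        below = (ens.spectra <= os.values[None, :]).sum(axis=0)
        p = 2.0 * (np.minimum(above, below) + 1) / (n + 1)
        p = np.minimum(p, 1.0)
    else:
        raise ParameterError(f"unknown pvalue_method {pvalue_method!r}")
    significant, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    bands = _contiguous_bands(os.frequencies, significant)
    verdict = "null_rejected" if significant.any() else "null_not_rejected"
    return SignificanceReport(
        frequencies=os.frequencies, z=z, p=p, q=q,
        significant=significant, bands=bands, alpha=float(alpha),
        verdict=verdict,
    )
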