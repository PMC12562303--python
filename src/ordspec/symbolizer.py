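"""Ordinal-pattern symbolization of univariate time series.

A window of ``D`` samples spaced ``tau`` apart is mapped to the permutation
that sorts it ascending, and the permutation is encoded as its 1-based
lexicographic rank: the fully ascending window gets code 1 and the fully
descending window gets code ``D!``, so the two monotone patterns sit at the
opposite ends of the code range.  The encoding depends only on the rank order
of the samples, hence is invariant under any strictly increasing transform of
the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ParameterError

__all__ = [
    "TimeSeries",
    "EmbeddingParams",
    "SymbolSequence",
    "rank_permutation",
    "symbolize",
    "select_delay",
    "check_length",
    "as_values",
]

#: Supported embedding dimensions.  D! must stay small enough that the
#: D!-state symbol alphabet can be sampled by realistic series lengths.
D_MIN, D_MAX = 2, 7

#: Magnitude of the tie-breaking jitter, relative to the value range.
JITTER_SCALE = 1e-12


@dataclass(frozen=True)
class TimeSeries:
    """A univariate real-valued series with an optional sampling interval."""

    values: np.ndarray
    sample_interval: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("time series must be one-dimensional")
        if v.size < 2:
            raise InvalidInputError("time series must contain at least 2 samples")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise InvalidInputError(f"non-finite value at index {bad}")
        if not self.sample_interval > 0:
            raise ParameterError("sample_interval must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def as_values(series) -> np.ndarray:
    """Coerce a TimeSeries or array-like to a validated 1-d float array."""
    if isinstance(series, TimeSeries):
        return series.values
    return TimeSeries(np.asarray(series, dtype=float)).values


@dataclass(frozen=True)
class EmbeddingParams:
    """Ordinal embedding dimension ``D`` and delay ``tau`` (in samples)."""

    D: int
    tau: int = 1

    def __post_init__(self):
        if not (D_MIN <= int(self.D) <= D_MAX):
            raise ParameterError(
                f"embedding dimension D={self.D} outside supported range "
                f"[{D_MIN}, {D_MAX}]"
            )
        if int(self.tau) < 1:
            raise ParameterError(f"delay tau={self.tau} must be a positive integer")
        object.__setattr__(self, "D", int(self.D))
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.D)


@dataclass(frozen=True)
class SymbolSequence:
    """Integer-coded ordinal-pattern sequence with its embedding parameters.

    ``codes`` take values in {1, ..., D!} and have length
    ``L = T - (D-1)*tau`` for a source series of length ``T``.
    """

    codes: np.ndarray
    params: EmbeddingParams = field(default_factory=lambda: EmbeddingParams(3, 1))

    def __post_init__(self):
        c = np.asarray(self.codes, dtype=np.int64)
        if c.ndim != 1 or c.size == 0:
            raise InvalidInputError("symbol sequence must be a non-empty 1-d array")
        if c.min() < 1 or c.max() > self.params.n_patterns:
            raise InvalidInputError(
                f"codes must lie in {{1,...,{self.params.n_patterns}}}"
            )
        object.__setattr__(self, "codes", c)

    def __len__(self) -> int:
        return self.codes.size

    @property
    def D(self) -> int:
        return self.params.D

    @property
    def tau(self) -> int:
        return self.params.tau


def _lehmer_ranks(perms: np.ndarray) -> np.ndarray:
    """1-based lexicographic rank of each permutation row (Lehmer code)."""
    D = perms.shape[1]
    fact = np.array([math.factorial(D - 1 - i) for i in range(D)], dtype=np.int64)
    # c[t, i] = number of positions j > i with perm[t, j] < perm[t, i]
    later_smaller = perms[:, None, :] < perms[:, :, None]  # [t, i, j]: p_j < p_i
    upper = np.triu(np.ones((D, D), dtype=bool), k=1)
    c = np.sum(later_smaller & upper[None, :, :], axis=2)
    return (c @ fact) + 1


def _apply_jitter(values: np.ndarray, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    vrange = float(np.ptp(values)) or 1.0
    return values + rng.uniform(-1.0, 1.0, size=values.shape) * JITTER_SCALE * vrange


def rank_permutation(window, tie_rule: str = "stable", seed=None) -> int:
    """Ordinal code (1-based lexicographic rank) of a single window.

    Parameters
    ----------
    window : sequence of D finite reals
    tie_rule : {"stable", "jitter"}
        "stable" orders equal values by temporal index (earlier first);
        "jitter" perturbs the window by seeded noise of relative magnitude
        1e-12 before ranking.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise InvalidInputError("window must be one-dimensional")
    if not np.all(np.isfinite(w)):
        raise InvalidInputError("window contains non-finite values")
    if not (D_MIN <= w.size <= D_MAX):
        raise ParameterError(
            f"window length {w.size} outside supported range [{D_MIN}, {D_MAX}]"
        )
    if tie_rule == "jitter":
        w = _apply_jitter(w, seed)
    elif tie_rule != "stable":
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    perm = np.argsort(w, kind="stable")[None, :]
    return int(_lehmer_ranks(perm)[0])


def check_length(T: int, D: int) -> bool:
    """Whether a series of length ``T`` samples the D!-pattern alphabet densely
    enough for reliable probability estimation (rule of thumb T >= (D+1)!)."""
    return int(T) >= math.factorial(int(D) + 1)


def symbolize(series, params: EmbeddingParams, tie_rule: str = "stable",
              seed=None) -> SymbolSequence:
    """Map a series onto its ordinal-pattern symbol sequence.

    The code at position ``t`` encodes the rank order of the delay vector
    ``(X_t, X_{t+tau}, ..., X_{t+(D-1)tau})``; the output has
    ``L = T - (D-1)*tau`` codes.
    """
    x = as_values(series)
    D, tau = params.D, params.tau
    T = x.size
    span = (D - 1) * tau
    if T < span + 2:
        raise InvalidInputError(
            f"series of length {T} too short for D={D}, tau={tau} "
            f"(needs at least {span + 2} samples)"
        )
    if not check_length(T, D):
        warnings.warn(
            f"series length T={T} < (D+1)! = {math.factorial(D + 1)}; "
            "ordinal-pattern probabilities may be poorly sampled",
            UserWarning,
            stacklevel=2,
        )
    if tie_rule == "jitter":
        x = _apply_jitter(x, seed)
    elif tie_rule != "stable":
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    L = T - span
    idx = np.arange(L)[:, None] + tau * np.arange(D)[None, :]
    windows = x[idx]
    perms = np.argsort(windows, axis=1, kind="stable")
    codes = _lehmer_ranks(perms)
    return SymbolSequence(codes=codes, params=params)


def select_delay(series, max_lag: int) -> int:
    """Choose the embedding delay from the sample autocorrelation function.

    Returns the smaller of the first zero crossing and the first local minimum
    of the sample ACF (ties go to the zero crossing).  A lag counts as a zero
    crossing when the sample ACF drops below the white-noise 95% band
    1.96/sqrt(T), since a finite-sample ACF rarely hits zero exactly.  If
    neither criterion exists within ``max_lag`` — the ACF decays monotonically
    and stays positive — the folding time is used instead: the smallest lag
    with rho <= 1/e.  If no criterion fires, ``max_lag`` is returned with a
    warning.  The result is never smaller than 1.
    """
    from statsmodels.tsa.stattools import acf

    x = as_values(series)
    max_lag = int(max_lag)
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    if max_lag >= x.size / 2:
        raise ParameterError(
            f"max_lag={max_lag} must be smaller than half the series length"
        )
    rho = acf(x, nlags=max_lag, fft=True)
    zero_band = 1.96 / math.sqrt(x.size)

    zero_cross = None
    for m in range(1, max_lag + 1):
        if rho[m] <= zero_band:
            zero_cross = m
            break
    local_min = None
    for m in range(1, max_lag):
        if rho[m] < rho[m - 1] and rho[m] < rho[m + 1]:
            local_min = m
            break

    candidates = [c for c in (zero_cross, local_min) if c is not None]
    if candidates:
        return max(1, min(candidates))
    # monotone positive ACF: folding time
    below = np.flatnonzero(rho[1:] <= 1.0 / math.e)
    if below.size:
        return max(1, int(below[0]) + 1)
    warnings.warn(
        f"no delay-selection criterion satisfied within max_lag={max_lag}; "
        "returning max_lag",
        UserWarning,
        stacklevel=2,
    )
    return max_lag
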