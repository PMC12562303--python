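"""Symbolic Markov-chain statistics of an ordinal-pattern sequence.

The symbol sequence is treated as a finite-state chain over the D! ordinal
patterns.  Because the lexicographic enumeration orders the patterns from
fully ascending (code 1) to fully descending (code D!), the integer codes
carry a meaningful rank scale, and the chain admits a rank mean, variance and
autocovariance:

    E{S}    = sum_i i * p_i
    Var(S)  = sum_i i^2 * p_i - E{S}^2
    Cov(m)  = sum_ij i * j * p(S_t = i, S_{t+m} = j) - E{S}^2

with p the stationary (occupation) probabilities.  The lag-m joint is either
taken from the fitted first-order chain (m-th power of the one-step
transition matrix, the default) or counted directly at each lag.
``Cov(0) == Var(S)`` holds exactly because the lag-0 joint is diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ParameterError
from .symbolizer import SymbolSequence

__all__ = [
    "TransitionModel",
    "RankAutocovariance",
    "estimate_stationary",
    "estimate_transition",
    "transition_model",
    "rank_autocovariance",
    "chapman_kolmogorov_diagnostic",
]

DEFAULT_MAX_LAG = 512


def estimate_stationary(seq: SymbolSequence) -> np.ndarray:
    """Occupation frequencies over the D! pattern codes (unobserved -> 0)."""
    n = seq.params.n_patterns
    counts = np.bincount(seq.codes, minlength=n + 1)[1:]
    return counts / seq.codes.size


def estimate_transition(seq: SymbolSequence, m: int):
    """Joint and conditional pattern probabilities at lag ``m``.

    Returns
    -------
    joint : (D!, D!) array
        ``joint[i-1, j-1]`` is the fraction of the ``L - m`` ordered pairs
        ``(S_t = i, S_{t+m} = j)``.
    conditional : (D!, D!) array
        Rows of ``joint`` normalized to sum to 1; rows with no mass are
        left at zero.
    occupied : (D!,) boolean array
        Which rows carry mass (pattern ``i`` observed among pair starts).
    """
    L = len(seq)
    m = int(m)
    if not 1 <= m <= L - 1:
        raise ParameterError(f"lag m={m} outside valid range [1, {L - 1}]")
    n = seq.params.n_patterns
    a = seq.codes[:-m] - 1
    b = seq.codes[m:] - 1
    joint = np.zeros((n, n))
    np.add.at(joint, (a, b), 1.0)
    joint /= L - m
    row_sums = joint.sum(axis=1)
    occupied = row_sums > 0
    conditional = np.zeros_like(joint)
    conditional[occupied] = joint[occupied] / row_sums[occupied, None]
    return joint, conditional, occupied


@dataclass(frozen=True)
class TransitionModel:
    """Stationary distribution plus per-lag conditional transition matrices."""

    stationary: np.ndarray
    lags: tuple
    transitions: dict = field(repr=False)
    occupied: np.ndarray = field(repr=False)


def transition_model(seq: SymbolSequence, lags) -> TransitionModel:
    """Estimate the chain's stationary distribution and the m-step
    transition matrices (by direct pair counting) at the requested lags."""
    stationary = estimate_stationary(seq)
    transitions = {}
    occupied = stationary > 0
    for m in lags:
        _, cond, _ = estimate_transition(seq, m)
        transitions[int(m)] = cond
    return TransitionModel(
        stationary=stationary,
        lags=tuple(int(m) for m in lags),
        transitions=transitions,
        occupied=occupied,
    )


def chapman_kolmogorov_diagnostic(seq: SymbolSequence, m: int) -> float:
    """Maximum absolute difference between the directly counted m-step
    transition matrix and the m-th power of the one-step matrix.

    Large values flag departures from first-order Markov structure — expected
    to some degree for ordinal sequences, whose patterns overlap in time.
    Use it to judge how much the default "markov" autocovariance estimator
    smooths over genuine higher-order dependence.
    """
    _, p1, occ = estimate_transition(seq, 1)
    _, pm, _ = estimate_transition(seq, m)
    powered = np.linalg.matrix_power(p1, int(m))
    return float(np.max(np.abs(powered[occ] - pm[occ])))


@dataclass(frozen=True)
class RankAutocovariance:
    """Rank autocovariance Cov(m), m = 0..N-1, of a coded symbol sequence."""

    cov: np.ndarray
    variance: float
    mean_rank: float
    method: str = "markov"
    normalization: str = "biased"

    @property
    def max_lag(self) -> int:
        return self.cov.size

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([np.arange(self.max_lag), self.cov]),
            fmt=("%d", "%.17g"),
            delimiter="\t",
            header="lag\tcovariance",
            comments="",
        )


def _counting_cov(s: np.ndarray, max_lag: int, normalization: str) -> np.ndarray:
    """Plug-in Cov(m) from the empirical joint at each lag (global mean).

    Equals the double sum over the lag-m pair frequencies, computed as
    ``(sum_t s_t s_{t+m}) / (L - m) - E^2``; the "biased" option then scales
    lag ``m`` by ``(L - m)/L``, which tames high-lag noise and keeps the
    sequence close to positive semidefinite.
    """
    L = s.size
    mean_rank = s.mean()
    e2 = mean_rank**2
    cov = np.empty(max_lag)
    cov[0] = np.mean(s * s) - e2
    for m in range(1, max_lag):
        c = float(s[:-m] @ s[m:]) / (L - m) - e2
        if normalization == "biased":
            c *= (L - m) / L
        cov[m] = c
    return cov


def _markov_cov(seq: SymbolSequence, max_lag: int) -> np.ndarray:
    """Cov(m) of the fitted first-order chain: the m-step joint is
    ``p_i (P1^m)_ij``, evaluated by repeated matrix-vector products."""
    n = seq.params.n_patterns
    p = estimate_stationary(seq)
    _, p1, _ = estimate_transition(seq, 1)
    ranks = np.arange(1, n + 1, dtype=float)
    mean_rank = p @ ranks
    e2 = mean_rank**2
    cov = np.empty(max_lag)
    cov[0] = p @ (ranks * ranks) - e2
    w = p * ranks  # w_m[j] = sum_i i * p_i * (P1^m)_ij
    for m in range(1, max_lag):
        w = w @ p1
        cov[m] = w @ ranks - e2
    return cov


def rank_autocovariance(seq: SymbolSequence, max_lag: int | None = None,
                        method: str = "markov",
                        normalization: str = "biased") -> RankAutocovariance:
    """Rank mean/variance and autocovariance up to lag ``max_lag - 1``.

    Two estimators of the lag-m joint pattern probabilities are available:

    ``method="markov"`` (default)
        Fit the one-step transition matrix from consecutive symbols and take
        its m-th power, per the first-order chain model of the symbolic
        dynamics.  All lags inherit the (well-sampled) one-step structure,
        so Cov(m) is smooth and decays geometrically for mixing chains while
        remaining exactly periodic for cyclic ones.
    ``method="counting"``
        Count symbol pairs at each lag directly; ``normalization`` selects
        the plain plug-in estimate ("unbiased") or its (L-m)/L-scaled
        variant ("biased").  This makes no Markov assumption but is noisy at
        high lags.

    ``Cov(0) == Var(S)`` exactly under either estimator.
    """
    if method not in ("markov", "counting"):
        raise ParameterError(f"unknown method {method!r}")
    if normalization not in ("biased", "unbiased"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    s = seq.codes.astype(float)
    L = s.size
    if max_lag is None:
        max_lag = min(L, DEFAULT_MAX_LAG)
    max_lag = int(max_lag)
    if not 1 <= max_lag <= L:
        raise ParameterError(f"max_lag={max_lag} outside valid range [1, {L}]")

    mean_rank = float(s.mean())
    variance = float(np.mean(s * s) - mean_rank**2)
    if method == "markov" and L >= 2:
        cov = _markov_cov(seq, max_lag)
    else:
        cov = _counting_cov(s, max_lag, normalization)
    if not np.all(np.isfinite(cov)):
        raise InvalidInputError("non-finite rank autocovariance")
    return RankAutocovariance(
        cov=cov, variance=variance, mean_rank=mean_rank,
        method=method, normalization=normalization,
    )
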