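"""Synthetic test systems: deterministic maps and flows with well-known
periodic/chaotic regimes, and stochastic processes that are *not* chaotic but
can fool linear spectral analysis.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import GenerationError, ParameterError

__all__ = [
    "logistic",
    "rossler_x",
    "gaussian_noise",
    "powerlaw_noise",
    "nonlinear_nongaussian",
    "tanh2_ar",
    "fundamental_period",
    "GENERATORS",
]

_DIVERGENCE_LIMIT = 1e6


def logistic(r: float = 4.0, T: int = 2000, burn_in: int = 1000,
             x0: float | None = None, seed=None) -> np.ndarray:
    """Logistic map x_{n+1} = r x_n (1 - x_n).

    The map period-doubles to chaos at r ~ 3.56995; r=3.55 and r=3.739 sit in
    periodic windows, r=3.8 and r=4 are chaotic.  ``x0`` defaults to a seeded
    uniform draw in (0.01, 0.99) to stay clear of the unstable fixed points.
    """
    if not 0 < r <= 4:
        raise ParameterError("logistic map requires 0 < r <= 4")
    if T <= 0 or burn_in < 0:
        raise ParameterError("T must be positive and burn_in non-negative")
    if x0 is None:
        x0 = float(np.random.default_rng(seed).uniform(0.01, 0.99))
    if not 0 < x0 < 1:
        raise ParameterError("x0 must lie in (0, 1)")
    x = x0
    out = np.empty(T)
    for n in range(burn_in + T):
        x = r * x * (1.0 - x)
        if not 0.0 <= x <= 1.0:
            raise GenerationError(f"logistic orbit escaped [0,1] at step {n}")
        if n >= burn_in:
            out[n - burn_in] = x
    return out


def _rossler_rhs(x, y, z, a):
    return -y - z, x + a * y, 2.0 + z * (x - 4.0)


def rossler_x(a: float = 0.42, T: int = 10_000, burn_in: int = 1000,
              dt: float = 0.05, init=(1.0, 1.0, 0.0), seed=None) -> np.ndarray:
    """x-component of the Rossler-type flow
    dx/dt = -y - z, dy/dt = x + a y, dz/dt = 2 + z (x - 4),
    integrated with fixed-step fourth-order Runge-Kutta, one sample per step.

    The flow is periodic at a = 0.30 and chaotic at a = 0.42 and a = 0.54
    (onset of chaos near a ~ 0.385).  ``seed`` is accepted for interface
    uniformity; the system is deterministic.
    """
    if not 0.25 <= a <= 0.55:
        raise ParameterError("control parameter a must lie in [0.25, 0.55]")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if T <= 0 or burn_in < 0:
        raise ParameterError("T must be positive and burn_in non-negative")
    x, y, z = (float(v) for v in init)
    out = np.empty(T)
    h = float(dt)
    for n in range(burn_in + T):
        k1x, k1y, k1z = _rossler_rhs(x, y, z, a)
        k2x, k2y, k2z = _rossler_rhs(x + 0.5 * h * k1x, y + 0.5 * h * k1y,
                                     z + 0.5 * h * k1z, a)
        k3x, k3y, k3z = _rossler_rhs(x + 0.5 * h * k2x, y + 0.5 * h * k2y,
                                     z + 0.5 * h * k2z, a)
        k4x, k4y, k4z = _rossler_rhs(x + h * k3x, y + h * k3y, z + h * k3z, a)
        x += (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        y += (h / 6.0) * (k1y + 2 * k2y + 2 * k3y + k4y)
        z += (h / 6.0) * (k1z + 2 * k2z + 2 * k3z + k4z)
        if abs(x) > _DIVERGENCE_LIMIT or abs(y) > _DIVERGENCE_LIMIT \
                or abs(z) > _DIVERGENCE_LIMIT:
            raise GenerationError(f"Rossler trajectory diverged at step {n}")
        if n >= burn_in:
            out[n - burn_in] = x
    return out


def gaussian_noise(T: int = 2000, seed=None) -> np.ndarray:
    """iid standard normal samples."""
    if T < 2:
        raise ParameterError("T must be >= 2")
    return np.random.default_rng(seed).standard_normal(T)


def powerlaw_noise(alpha: float = 1.0, T: int = 2000, seed=None) -> np.ndarray:
    """Colored noise with power spectrum S(f) proportional to f^(-alpha),
    built by spectral synthesis: Fourier amplitudes f^(-alpha/2), iid uniform
    phases, inverse transform, then standardized to zero mean, unit variance.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    if T < 2:
        raise ParameterError("T must be >= 2")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(T)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if T % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=T)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        return x
    return x / sd


def nonlinear_nongaussian(T: int = 2000, burn_in: int = 1000,
                          dt_index: float = 0.01, seed=None,
                          noise_gain: float = 0.0025) -> np.ndarray:
    """Nonlinear recursion driven by Laplacian noise:

        x_t = 0.5 x_{t-1} - 0.3 x_{t-2} + 0.1 y_{t-2}
              + 0.1 x_{t-2}^2 + 0.4 y_{t-1}^2 + g eta'_t
        y_t = sin(4 pi t) + sin(6 pi t) + g eta''_t

    with eta iid Laplace(mu=0, b=1) and gain g = 0.0025.  Time in the
    sinusoids is t_n = n * dt_index (default 0.01): on an integer grid both
    sinusoids would vanish identically, so a sub-integer time step is needed
    for the forcing to oscillate at all.
    """
    if T < 3:
        raise ParameterError("T must be >= 3")
    if burn_in < 0:
        raise ParameterError("burn_in must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = burn_in + T
    t = np.arange(n_total) * dt_index
    eta2 = rng.laplace(0.0, 1.0, size=n_total)
    y = np.sin(4 * np.pi * t) + np.sin(6 * np.pi * t) + noise_gain * eta2
    eta1 = rng.laplace(0.0, 1.0, size=n_total)
    x = np.zeros(n_total)
    for n in range(2, n_total):
        x[n] = (0.5 * x[n - 1] - 0.3 * x[n - 2] + 0.1 * y[n - 2]
                + 0.1 * x[n - 2] ** 2 + 0.4 * y[n - 1] ** 2
                + noise_gain * eta1[n])
        if abs(x[n]) > _DIVERGENCE_LIMIT:
            raise GenerationError(f"nonlinear recursion diverged at step {n}")
    return x[burn_in:]


def tanh2_ar(T: int = 2000, burn_in: int = 1000, seed=None) -> np.ndarray:
    """Static non-monotone transform x_t = tanh^2(y_t) of the linear
    non-Gaussian AR process

        y_t = 0.4 y_{t-3} - 0.3 y_{t-2} + 0.2 y_{t-1} + e_t,

    where e_t = U^2 with U ~ Uniform(-0.5, 0.5) (so e_t in [0, 0.25]).  The
    AR polynomial is stable (companion spectral radius < 1).  A correct
    surrogate test must *not* call this chaotic: x is a static transform of a
    linearly filtered noise, which is exactly the null hypothesis.
    """
    if T < 4:
        raise ParameterError("T must be >= 4")
    if burn_in < 0:
        raise ParameterError("burn_in must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = burn_in + T
    e = rng.uniform(-0.5, 0.5, size=n_total) ** 2
    y = np.zeros(n_total)
    for n in range(3, n_total):
        y[n] = 0.4 * y[n - 3] - 0.3 * y[n - 2] + 0.2 * y[n - 1] + e[n]
        if abs(y[n]) > _DIVERGENCE_LIMIT:
            raise GenerationError(f"AR recursion diverged at step {n}")
    return np.tanh(y[burn_in:]) ** 2


def fundamental_period(x, detrend: str = "constant") -> float:
    """Dominant cycle length in samples, located as the peak of the classical
    periodogram (excluding the zero-frequency bin)."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ParameterError("series too short for a periodogram")
    freqs, pxx = signal.periodogram(x, detrend=detrend)
    k = 1 + int(np.argmax(pxx[1:]))
    if freqs[k] == 0:
        raise GenerationError("no nonzero-frequency periodogram peak found")
    return 1.0 / freqs[k]


#: Name -> callable registry used by the CLI's ``generate`` subcommand.
GENERATORS = {
    "logistic": logistic,
    "rossler_x": rossler_x,
    "gaussian": gaussian_noise,
    "powerlaw": powerlaw_noise,
    "nonlinear_nongaussian": nonlinear_nongaussian,
    "tanh2_ar": tanh2_ar,
}

# Stability of the tanh2_ar linear part, checked once at import time.
_companion_roots = np.roots([1.0, -0.2, 0.3, -0.4])
assert np.max(np.abs(_companion_roots)) < 1.0
del _companion_roots
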