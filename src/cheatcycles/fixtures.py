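"""Synthetic time series for exercising the analysis stack without simulations."""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DomainError

__all__ = ["make_sine_series", "make_logistic_series"]


def make_sine_series(
    amplitude: float,
    period: float,
    noise_sd: float = 0.0,
    length: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """Noisy sinusoid around 0.5: ``0.5 + amplitude sin(2 pi t / period) + eps``.

    ``eps ~ Normal(0, noise_sd)`` with a generator seeded by ``seed``. Values
    that leave [0, 1] trigger a warning but are not clipped.
    """
    if period < 2:
        raise DomainError(f"period must be >= 2, got {period}")
    if length < period:
        raise DomainError(f"length ({length}) must be >= period ({period})")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    t = np.arange(length, dtype=float)
    y = 0.5 + amplitude * np.sin(2.0 * np.pi * t / period)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, length)
    if np.any(y < 0) or np.any(y > 1):
        warnings.warn("series leaves [0, 1]; values are not clipped", stacklevel=2)
    return y


def make_logistic_series(
    n0: float = 0.1,
    r: float = 1.0,
    K: float = 10.0,
    duration: float = 10.0,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form logistic trajectory ``K n0 e^{rt} / (K + n0 (e^{rt} - 1))``.

    Returns ``(times, densities)``; handy as an exact oracle for the ODE
    integrator.
    """
    if n0 < 0 or K <= 0 or duration <= 0 or dt <= 0:
        raise DomainError("require n0 >= 0, K > 0, duration > 0, dt > 0")
    t = np.arange(0.0, duration + dt / 2, dt)
    e = np.exp(r * t)
    return t, K * n0 * e / (K + n0 * (e - 1.0))
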