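"""Periodicity statistics for per-cycle time series.

Two complementary detectors: harmonic regression (OLS fit of one sine/cosine
pair per candidate period, with delta-method confidence intervals on the
amplitude) and the discrete-Fourier-transform amplitude (largest single-tone
amplitude after mean-centering). Both agree exactly on a pure tone whose
period is in the candidate grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "HarmonicFit",
    "harmonic_regression",
    "peak_period",
    "dft_amplitude",
    "amplitude_sweep",
    "SweepResult",
    "default_period_grid",
]


def default_period_grid(n_points: int) -> np.ndarray:
    """Integer candidate periods 2 .. n_points // 2 (at least 2)."""
    upper = max(2, n_points // 2)
    return np.arange(2, upper + 1, dtype=float)


@dataclass(frozen=True)
class HarmonicFit:
    """Amplitude spectrum from per-period harmonic regression.

    ``amplitudes[i]`` is the fitted amplitude at ``periods[i]`` with 95%
    bounds ``ci_low[i]``/``ci_high[i]``. ``peak_period`` is the period of
    maximal amplitude (smallest period on ties); None when every amplitude is
    zero. ``degenerate`` marks a (near-)constant input series whose CIs carry
    no information.
    """

    periods: np.ndarray
    amplitudes: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    peak_period: float | None
    degenerate: bool = False

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(self.amplitudes))


def harmonic_regression(series, periods=None) -> HarmonicFit:
    """Fit ``y_t = c + A sin(2 pi t / T) + B cos(2 pi t / T)`` for each period T.

    Amplitude is ``sqrt(A^2 + B^2)``; its 95% CI comes from the delta method
    applied to the OLS coefficient covariance. ``t`` is the 0-based sample
    index, so periods are expressed in samples (growth cycles).
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise DomainError("series must be 1-D with at least 3 points")
    if np.any(np.isnan(y)):
        raise DomainError("series contains NaN; trim or impute first")
    if periods is None:
        periods = default_period_grid(len(y))
    periods = np.asarray(periods, dtype=float)
    if np.any(periods < 2):
        raise DomainError("candidate periods must be >= 2 samples")

    t = np.arange(len(y), dtype=float)
    n = len(y)
    dof = n - 3
    degenerate = np.ptp(y) == 0.0
    z = stats.norm.ppf(0.975)

    amps = np.zeros_like(periods)
    lo = np.zeros_like(periods)
    hi = np.zeros_like(periods)
    for k, T in enumerate(periods):
        if degenerate:
            break  # a constant series has exactly zero amplitude everywhere
        w = 2.0 * np.pi / T
        X = np.column_stack([np.ones(n), np.sin(w * t), np.cos(w * t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        A, B = coef[1], coef[2]
        amp = float(np.hypot(A, B))
        amps[k] = amp
        if dof <= 0:
            continue
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        if amp > 0:
            g = np.array([0.0, A / amp, B / amp])
            se = float(np.sqrt(g @ cov @ g))
        else:  # gradient undefined at 0; fall back to the larger coefficient se
            se = float(np.sqrt(max(cov[1, 1], cov[2, 2])))
        lo[k] = max(0.0, amp - z * se)
        hi[k] = amp + z * se

    if np.all(amps == 0.0):
        peak = None
    else:
        best = np.flatnonzero(amps == amps.max())
        peak = float(periods[best].min())
    return HarmonicFit(
        periods=periods,
        amplitudes=amps,
        ci_low=lo,
        ci_high=hi,
        peak_period=peak,
        degenerate=degenerate,
    )


def peak_period(fit: HarmonicFit) -> float:
    """Period of maximal fitted amplitude; smallest on ties.

    Raises :class:`DomainError` for an all-zero (undefined-peak) fit.
    """
    if fit.peak_period is None:
        raise DomainError("all amplitudes are zero; peak period undefined")
    return fit.peak_period


def dft_amplitude(series) -> float:
    """Largest single-tone amplitude of a mean-centered series.

    Computes the DFT of ``y - mean(y)`` and returns
    ``max_k 2 |X_k| / L`` over nonzero frequencies, i.e. the amplitude of the
    dominant sinusoid. Requires at least 4 samples.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise DomainError("series must be 1-D with at least 4 points")
    if np.any(np.isnan(y)):
        raise DomainError("series contains NaN; trim or impute first")
    spec = np.fft.rfft(y - y.mean())
    return float(np.max(2.0 * np.abs(spec[1:]) / len(y)))


@dataclass
class SweepResult:
    """Grid sweep output: one matrix per statistic, shape (len(a), len(b)).

    ``matrices[name][i, j]`` averages statistic ``name`` over replicates at
    ``(a_grid[i], b_grid[j])``; failed runs leave NaN cells and are listed in
    ``failures`` as ``(a, b, replicate, message)``. ``long`` holds every
    per-replicate value as ``(a, b, replicate, name, value)`` tuples.
    """

    a_grid: np.ndarray
    b_grid: np.ndarray
    matrices: dict[str, np.ndarray]
    long: list[tuple]
    failures: list[tuple]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.long, columns=["a", "b", "replicate", "statistic", "value"]
        )


def amplitude_sweep(
    a_grid,
    b_grid,
    runner: Callable[[float, float, int], Mapping[str, float]],
    replicates: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Average a scenario engine's statistics over an (a, b) grid.

    ``runner(a, b, seed) -> {statistic: value}`` is called ``replicates``
    times per cell with child seeds spawned deterministically from ``seed``.
    A runner exception marks that replicate failed; the cell mean is taken
    over the remaining replicates (NaN if none succeeded).
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    a_grid = np.asarray(a_grid, dtype=float)
    b_grid = np.asarray(b_grid, dtype=float)
    ss = np.random.SeedSequence(seed)
    child_seeds = [
        int(s.generate_state(1)[0])
        for s in ss.spawn(len(a_grid) * len(b_grid) * replicates)
    ]

    cells: dict[str, list[list[list[float]]]] = {}
    long: list[tuple] = []
    failures: list[tuple] = []
    idx = 0
    per_cell: list[list[dict[str, list[float]]]] = [
        [dict() for _ in b_grid] for _ in a_grid
    ]
    for i, a in enumerate(a_grid):
        for j, b in enumerate(b_grid):
            for rep in range(replicates):
                s = child_seeds[idx]
                idx += 1
                try:
                    out = runner(float(a), float(b), s)
                except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                    failures.append((float(a), float(b), rep, str(exc)))
                    continue
                for name, val in out.items():
                    per_cell[i][j].setdefault(name, []).append(float(val))
                    long.append((float(a), float(b), rep, name, float(val)))

    names = sorted({name for row in per_cell for cell in row for name in cell})
    matrices = {
        name: np.full((len(a_grid), len(b_grid)), np.nan) for name in names
    }
    for i in range(len(a_grid)):
        for j in range(len(b_grid)):
            for name, vals in per_cell[i][j].items():
                vals = [v for v in vals if not np.isnan(v)]
                if vals:
                    matrices[name][i, j] = float(np.mean(vals))
    return SweepResult(
        a_grid=a_grid, b_grid=b_grid, matrices=matrices, long=long, failures=failures
    )
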