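"""Deterministic growth dynamics of one well-mixed cooperator-cheat population.

The cooperator grows logistically with joint population regulation; the cheat
grows at the same regulated rate rescaled by the benefit coefficient ``h`` and
by two sigmoid modifiers: one increasing with cooperator *density* (weight
``a``) and one increasing with cooperator *frequency* (weight ``b``). With
equal between-strain regulation (``alpha = 1``) every state on the line
``N_co + N_ch = K`` is stationary, so the chemostat-like system always relaxes
to that line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .errors import DomainError, IntegrationError, ParameterError
from .params import DEFAULT_SOLVER, ModelParams, SolverSettings

__all__ = [
    "PopulationState",
    "Trajectory",
    "density_modifier",
    "frequency_modifier",
    "derivatives",
    "integrate_growth",
    "vector_field",
]


class PopulationState(NamedTuple):
    """Cooperator and cheat densities; behaves as a plain ``(N_co, N_ch)`` pair."""

    n_co: float
    n_ch: float


@dataclass(frozen=True)
class Trajectory:
    """Time course of a single growth phase.

    Attributes
    ----------
    times : ndarray
        Strictly increasing time points.
    n_co, n_ch : ndarray
        Cooperator / cheat densities at each time point, non-negative.
    """

    times: np.ndarray
    n_co: np.ndarray
    n_ch: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.n_co) or len(self.times) != len(self.n_ch):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        return self.n_co + self.n_ch

    @property
    def p_cheat(self) -> np.ndarray:
        """Cheat proportion; NaN where the population is empty (0/0 undefined)."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_ch / np.where(tot > 0, tot, 1.0), np.nan)

    @property
    def states(self) -> list[PopulationState]:
        return [PopulationState(co, ch) for co, ch in zip(self.n_co, self.n_ch)]

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(float(self.n_co[-1]), float(self.n_ch[-1]))

    def to_dataframe(self):
        """Tidy frame with columns ``time, N_co, N_ch, p_cheat``."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "N_co": self.n_co,
                "N_ch": self.n_ch,
                "p_cheat": self.p_cheat,
            }
        )


def density_modifier(n_co, a: float, s_d: float, t_d: float):
    """Cheat density-dependence multiplier ``1 - a + a / (1 + exp(-s_d (N_co - t_d)))``.

    Bounded in ``[1 - a, 1]`` and non-decreasing in ``n_co``; identically 1
    when the weighting ``a`` is 0. Accepts scalars or arrays.
    """
    if not 0 <= a <= 1:
        raise ParameterError(f"a must be in [0, 1], got {a}")
    return 1.0 - a + a * expit(s_d * (np.asarray(n_co, dtype=float) - t_d))


def frequency_modifier(p_co, b: float, s_f: float, t_f: float):
    """Cheat frequency-dependence multiplier ``1 - b + b / (1 + exp(-s_f (p_co - t_f)))``.

    ``p_co`` is the cooperator proportion ``N_co / (N_co + N_ch)`` and must lie
    in [0, 1]. Bounded in ``[1 - b, 1]``, non-decreasing in ``p_co``, and
    identically 1 when ``b`` is 0.
    """
    if not 0 <= b <= 1:
        raise ParameterError(f"b must be in [0, 1], got {b}")
    p = np.asarray(p_co, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError(f"p_co must be in [0, 1], got {p_co}")
    return 1.0 - b + b * expit(s_f * (p - t_f))


def derivatives(state, params: ModelParams) -> tuple[float, float]:
    """Instantaneous rates ``(dN_co/dt, dN_ch/dt)``.

    The empty state (both densities zero) is an absorbing fixed point; the
    frequency modifier is never evaluated there.
    """
    n_co, n_ch = float(state[0]), float(state[1])
    if n_co < 0 or n_ch < 0:
        raise DomainError(f"densities must be non-negative, got ({n_co}, {n_ch})")
    total = n_co + n_ch
    if total == 0.0:
        return (0.0, 0.0)
    d_co = params.r * n_co * (1.0 - (n_co + params.alpha * n_ch) / params.K)
    mod = density_modifier(n_co, params.a, params.s_d, params.t_d)
    mod *= frequency_modifier(n_co / total, params.b, params.s_f, params.t_f)
    d_ch = (
        mod
        * params.h
        * params.r
        * n_ch
        * (1.0 - (params.alpha * n_co + n_ch) / params.K)
    )
    return (float(d_co), float(d_ch))


def _rhs(params: ModelParams):
    """Vectorized right-hand side for the solver; clips transient negatives."""
    r, K, alpha, h = params.r, params.K, params.alpha, params.h
    a, s_d, t_d = params.a, params.s_d, params.t_d
    b, s_f, t_f = params.b, params.s_f, params.t_f

    def f(t, y):
        n_co = y[0] if y[0] > 0.0 else 0.0
        n_ch = y[1] if y[1] > 0.0 else 0.0
        total = n_co + n_ch
        if total <= 0.0:
            return [0.0, 0.0]
        d_co = r * n_co * (1.0 - (n_co + alpha * n_ch) / K)
        mod = 1.0 - a + a * expit(s_d * (n_co - t_d))
        mod *= 1.0 - b + b * expit(s_f * (n_co / total - t_f))
        d_ch = mod * h * r * n_ch * (1.0 - (alpha * n_co + n_ch) / K)
        return [d_co, d_ch]

    return f


def _clip_floor(arr: np.ndarray, floor: float) -> np.ndarray:
    """Zero out solver undershoot: values below ``floor`` become exactly 0."""
    out = np.asarray(arr, dtype=float).copy()
    out[out < floor] = 0.0
    return out


def integrate_growth(
    state0,
    params: ModelParams,
    duration: float,
    solver: SolverSettings | None = None,
    *,
    end_state_only: bool = False,
):
    """Integrate the growth dynamics for ``duration`` time units.

    Parameters
    ----------
    state0 : (float, float)
        Initial ``(N_co, N_ch)``, both non-negative.
    params : ModelParams
    duration : float
        Growth time (> 0).
    solver : SolverSettings, optional
        Tolerances, method, and the dense-output sampling interval ``dt``.
    end_state_only : bool
        If True, skip dense output and return just the final
        :class:`PopulationState` (used by the metapopulation engine).

    Returns
    -------
    Trajectory or PopulationState
        Sampled at ``0, dt, 2 dt, ..., duration`` (the endpoint is always
        included), with densities clipped to zero below the solver floor.
    """
    solver = solver or DEFAULT_SOLVER
    if duration <= 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    n_co0, n_ch0 = float(state0[0]), float(state0[1])
    if n_co0 < 0 or n_ch0 < 0:
        raise DomainError(f"initial densities must be non-negative, got {state0}")

    if end_state_only:
        t_eval = np.array([duration])
    else:
        t_eval = np.arange(0.0, duration, solver.dt)
        if duration - t_eval[-1] > 1e-12:
            t_eval = np.append(t_eval, duration)
        else:
            t_eval[-1] = duration

    sol = solve_ivp(
        _rhs(params),
        (0.0, duration),
        [n_co0, n_ch0],
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    n_co = _clip_floor(sol.y[0], solver.density_floor)
    n_ch = _clip_floor(sol.y[1], solver.density_floor)
    if end_state_only:
        return PopulationState(float(n_co[-1]), float(n_ch[-1]))
    return Trajectory(times=sol.t, n_co=n_co, n_ch=n_ch)


def vector_field(
    grid: Iterable[Sequence[float]],
    params: ModelParams,
    normalize: bool = False,
):
    """Evaluate the derivative field on a set of states.

    Returns ``(vectors, magnitudes)`` where ``vectors`` has shape (n, 2). With
    ``normalize=True`` each nonzero vector is scaled to unit length and its
    original Euclidean norm is kept in ``magnitudes``.
    """
    pts = np.atleast_2d(np.asarray(list(grid), dtype=float))
    vecs = np.array([derivatives(p, params) for p in pts], dtype=float)
    mags = np.linalg.norm(vecs, axis=1)
    if normalize:
        nz = mags > 0
        vecs[nz] /= mags[nz, None]
    return vecs, mags
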