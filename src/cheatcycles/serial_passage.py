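"""Serial-passage engine: deterministic growth phases punctuated by dilution.

Each cycle integrates the growth dynamics for ``tgrow`` time units and then
divides both densities by the dilution ratio ``D``. Densities stay real-valued
here; integerization is the metapopulation module's concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import PopulationState, Trajectory, integrate_growth
from .errors import ParameterError
from .params import DEFAULT_SOLVER, ModelParams, PassageParams, SolverSettings

__all__ = [
    "CycleRecord",
    "dilute",
    "run_serial_passage",
    "cheat_proportion_series",
    "stabilized_amplitude",
]

#: Both strains below this density => the run is flagged extinct and stops.
EXTINCTION_THRESHOLD = 1e-12


@dataclass(frozen=True)
class CycleRecord:
    """One growth-dilution cycle.

    ``end_state`` is the state at the end of the growth phase, *before*
    dilution; ``diluted_state`` seeds the next cycle. ``end_p_cheat`` is the
    cheat proportion at the end of growth (NaN if the population is empty) --
    dilution does not change it. ``trajectory`` is the dense within-cycle time
    course; it is None when trajectory recording is off.
    """

    index: int
    start_state: PopulationState
    end_state: PopulationState
    diluted_state: PopulationState
    end_p_cheat: float
    trajectory: Trajectory | None = None
    extinct: bool = False


def dilute(state, D: float) -> PopulationState:
    """Instantaneous bottleneck: divide both densities by ``D >= 1``."""
    if D < 1:
        raise ParameterError(f"dilution ratio D must be >= 1, got {D}")
    return PopulationState(float(state[0]) / D, float(state[1]) / D)


def run_serial_passage(
    model: ModelParams,
    passage: PassageParams,
    state0,
    solver: SolverSettings | None = None,
    *,
    record_trajectories: bool = True,
) -> list[CycleRecord]:
    """Run ``passage.n_cycles`` growth-dilution cycles from ``state0``.

    Deterministic and bit-reproducible for fixed solver settings. If both
    strains fall below the extinction threshold the run stops early and the
    final record carries ``extinct=True``.
    """
    solver = solver or DEFAULT_SOLVER
    records: list[CycleRecord] = []
    state = PopulationState(float(state0[0]), float(state0[1]))
    for c in range(passage.n_cycles):
        traj = integrate_growth(state, model, passage.tgrow, solver)
        end = traj.final_state
        diluted = dilute(end, passage.D)
        total = end.n_co + end.n_ch
        p = end.n_ch / total if total > 0 else float("nan")
        extinct = total < EXTINCTION_THRESHOLD
        records.append(
            CycleRecord(
                index=c,
                start_state=state,
                end_state=end,
                diluted_state=diluted,
                end_p_cheat=p,
                trajectory=traj if record_trajectories else None,
                extinct=extinct,
            )
        )
        if extinct:
            break
        state = diluted
    return records


def cheat_proportion_series(
    records: list[CycleRecord], burn_in_cycles: int = 0
) -> np.ndarray:
    """Concatenated within-cycle cheat-proportion series after a burn-in.

    Requires trajectories to have been recorded. The within-cycle series are
    concatenated in cycle order; NaN (empty-population) samples are kept.
    """
    kept = [r for r in records if r.index >= burn_in_cycles]
    if not kept:
        raise ValueError("burn-in leaves no cycles")
    if any(r.trajectory is None for r in kept):
        raise ValueError("trajectories were not recorded for all kept cycles")
    return np.concatenate([r.trajectory.p_cheat for r in kept])


def stabilized_amplitude(p_series, burn_in_cycles: int = 0) -> float:
    """Oscillation amplitude: max minus min cheat proportion after burn-in.

    ``p_series`` is either a flat array (then ``burn_in_cycles`` must be 0 and
    the whole series is used) or a sequence of per-cycle arrays, of which the
    first ``burn_in_cycles`` are discarded. NaN samples are ignored.
    """
    if isinstance(p_series, np.ndarray) and p_series.ndim == 1:
        if burn_in_cycles:
            raise ValueError(
                "burn_in_cycles requires per-cycle input; pass a sequence of arrays"
            )
        post = p_series
    else:
        cycles = list(p_series)
        if burn_in_cycles >= len(cycles):
            raise ValueError(
                f"burn-in of {burn_in_cycles} leaves no cycles out of {len(cycles)}"
            )
        post = np.concatenate([np.atleast_1d(np.asarray(c, float)) for c in cycles[burn_in_cycles:]])
    post = post[~np.isnan(post)]
    if post.size == 0:
        raise ValueError("no defined samples after burn-in")
    return float(np.max(post) - np.min(post))
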