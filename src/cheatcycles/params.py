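"""Parameter containers for the growth model, serial passage, and metapopulation.

All containers are frozen dataclasses validated at construction time so that
invalid parameterizations fail loudly before any simulation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ParameterError

#: Dimensionless product s_d * K used to derive a density-sigmoid steepness
#: that keeps the same shape (in units of K) at any carrying capacity.
_SD_TIMES_K = 20.0
#: Ratio t_d / K used to derive the density-sigmoid threshold. The threshold
#: must sit between the post-bottleneck density (K / D) and K for cheats to
#: lose early and gain late within a growth phase; K / 5 with the default
#: D = 10 puts it in the middle of that range (calibrated, see README).
_TD_OVER_K = 0.2


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-strain growth dynamics.

    Parameters
    ----------
    r : float
        Intrinsic growth rate per unit time (> 0).
    K : float
        Carrying capacity, in density units (> 0).
    alpha : float
        Relative strength of between-strain population regulation (>= 0);
        ``alpha = 1`` makes both strains regulate each other as strongly as
        themselves.
    h : float
        Benefit coefficient of cheating (>= 0); multiplies the cheat growth
        rate. ``h >= 1`` lets cheats out-grow cooperators when the density
        and frequency modifiers permit. The default 4.5 is calibrated so that
        the focal density-dependent setting (a=1, b=0, D=10) sits inside the
        oscillating regime, both deterministically (within-cycle cycles) and
        in the stochastic metapopulation (cross-cycle quasi-cycles with a
        10-20 cycle period and mean cheat fitness between 1 and 1.5).
    a : float
        Weighting of cheat density dependence, in [0, 1]; 0 disables it.
    b : float
        Weighting of cheat frequency dependence, in [0, 1]; 0 disables it.
    s_d : float or None
        Steepness of the density sigmoid (per density unit, >= 0). ``None``
        derives ``20 / K`` so the sigmoid shape is invariant in units of K
        (equals 2 at the default K = 10).
    t_d : float or None
        Threshold of the density sigmoid (density units, >= 0). ``None``
        derives ``K / 5`` (equals 2 at the default K = 10), between the
        post-bottleneck density K/D and K so that density-dependent selection
        switches sign within a growth phase.
    s_f : float
        Steepness of the frequency sigmoid (dimensionless, >= 0).
    t_f : float
        Threshold of the frequency sigmoid, a proportion in [0, 1].
    """

    r: float = 1.0
    K: float = 10.0
    alpha: float = 1.0
    h: float = 4.5
    a: float = 1.0
    b: float = 0.0
    s_d: float | None = None
    t_d: float | None = None
    s_f: float = 10.0
    t_f: float = 0.5

    def __post_init__(self) -> None:
        _check(self.r > 0, f"r must be > 0, got {self.r}")
        _check(self.K > 0, f"K must be > 0, got {self.K}")
        if self.s_d is None:
            object.__setattr__(self, "s_d", _SD_TIMES_K / self.K)
        if self.t_d is None:
            object.__setattr__(self, "t_d", _TD_OVER_K * self.K)
        _check(self.alpha >= 0, f"alpha must be >= 0, got {self.alpha}")
        _check(self.h >= 0, f"h must be >= 0, got {self.h}")
        _check(0 <= self.a <= 1, f"a must be in [0, 1], got {self.a}")
        _check(0 <= self.b <= 1, f"b must be in [0, 1], got {self.b}")
        _check(self.s_d >= 0, f"s_d must be >= 0, got {self.s_d}")
        _check(self.t_d >= 0, f"t_d must be >= 0, got {self.t_d}")
        _check(self.s_f >= 0, f"s_f must be >= 0, got {self.s_f}")
        _check(0 <= self.t_f <= 1, f"t_f must be in [0, 1], got {self.t_f}")

    def with_capacity(self, K_new: float) -> "ModelParams":
        """Return a copy rescaled to carrying capacity ``K_new``.

        The density-sigmoid threshold and steepness are rescaled so the
        sigmoid keeps the same shape in units of the carrying capacity
        (``t_d / K`` and ``s_d * K`` are preserved).
        """
        _check(K_new > 0, f"K must be > 0, got {K_new}")
        scale = K_new / self.K
        return dataclasses.replace(
            self, K=K_new, t_d=self.t_d * scale, s_d=self.s_d / scale
        )


@dataclass(frozen=True)
class PassageParams:
    """Serial-passage (growth-dilution cycle) settings.

    ``D`` is the dilution ratio applied instantaneously after every growth
    phase of duration ``tgrow``; ``burn_in_cycles`` cycles are discarded
    before summary statistics.
    """

    D: float = 10.0
    tgrow: float = 10.0
    n_cycles: int = 200
    burn_in_cycles: int = 50

    def __post_init__(self) -> None:
        _check(self.D >= 1, f"D must be >= 1, got {self.D}")
        _check(self.tgrow > 0, f"tgrow must be > 0, got {self.tgrow}")
        _check(self.n_cycles >= 1, f"n_cycles must be >= 1, got {self.n_cycles}")
        _check(
            0 <= self.burn_in_cycles < self.n_cycles,
            f"burn_in_cycles must be in [0, n_cycles), got {self.burn_in_cycles}",
        )


@dataclass(frozen=True)
class MetaPopParams:
    """Stochastic metapopulation settings.

    ``M`` subpopulations grow independently for ``tgrow`` per cycle, are
    partially mixed by ``round(F * M)`` pairwise events, and are then diluted
    by ``D``. ``K_sub`` (if given) rescales the growth model to a
    per-subpopulation carrying capacity via :meth:`ModelParams.with_capacity`.
    ``integer_mode`` selects how counts become integers, i.e. the source of
    demographic stochasticity: ``"binomial"`` (default; pooled pairs are split
    binomially between the two new subpopulations and the bottleneck is a
    binomial thinning with success probability ``1/D``), ``"stochastic"``
    (floor plus Bernoulli on the fractional part everywhere), ``"round"``
    (deterministic half-away-from-zero; note that identically initialized
    subpopulations then never diverge), or ``"none"`` (real-valued,
    deterministic limit).
    """

    M: int = 50
    K_sub: float | None = 40.0
    F: float = 2.0
    D: float = 10.0
    tgrow: float = 10.0
    n_cycles: int = 200
    burn_in_cycles: int = 50
    n0_co: int = 5
    n0_ch: int = 5
    seed: int = 0
    integer_mode: str = "binomial"

    def __post_init__(self) -> None:
        _check(self.M >= 2, f"M must be >= 2, got {self.M}")
        _check(self.F >= 0, f"F must be >= 0, got {self.F}")
        _check(self.D >= 1, f"D must be >= 1, got {self.D}")
        _check(self.tgrow > 0, f"tgrow must be > 0, got {self.tgrow}")
        _check(self.n_cycles >= 1, f"n_cycles must be >= 1, got {self.n_cycles}")
        _check(
            0 <= self.burn_in_cycles < self.n_cycles,
            f"burn_in_cycles must be in [0, n_cycles), got {self.burn_in_cycles}",
        )
        _check(self.n0_co >= 0, f"n0_co must be >= 0, got {self.n0_co}")
        _check(self.n0_ch >= 0, f"n0_ch must be >= 0, got {self.n0_ch}")
        if self.K_sub is not None:
            _check(self.K_sub > 0, f"K_sub must be > 0, got {self.K_sub}")
        _check(
            self.integer_mode in ("binomial", "round", "stochastic", "none"),
            f"integer_mode must be 'binomial', 'round', 'stochastic' or 'none', "
            f"got {self.integer_mode!r}",
        )


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive Runge-Kutta settings shared by every integration."""

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    dt: float = 0.01  # dense-output sampling interval
    density_floor: float = 1e-12  # outputs below this are clipped to 0

    def __post_init__(self) -> None:
        _check(self.rtol > 0, "rtol must be > 0")
        _check(self.atol > 0, "atol must be > 0")
        _check(self.dt > 0, "dt must be > 0")


DEFAULT_SOLVER = SolverSettings()
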