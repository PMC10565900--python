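"""Run configuration: YAML/JSON loading, validation, defaults, round-tripping.

A config file has optional blocks ``model``, ``passage``, ``meta``, ``solver``,
``init`` and ``analysis`` plus top-level ``scenario``, ``seed`` and ``out``.
Common knobs (``a b h D tgrow M F K cycles``) may also be given at top level
and are routed into the right blocks, so the minimal file
``{scenario: 2, a: 1, b: 0}`` is valid.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError
from .params import MetaPopParams, ModelParams, PassageParams, SolverSettings

__all__ = ["RunConfig", "load_config", "save_config"]

_MODEL_KEYS = {"r", "K", "alpha", "h", "a", "b", "s_d", "t_d", "s_f", "t_f"}
_PASSAGE_KEYS = {"D", "tgrow", "n_cycles", "burn_in_cycles"}
_META_KEYS = {
    "M", "K_sub", "F", "D", "tgrow", "n_cycles", "burn_in_cycles",
    "n0_co", "n0_ch", "seed", "integer_mode",
}
_SOLVER_KEYS = {"method", "rtol", "atol", "dt", "density_floor"}
# top-level shorthand -> (block, key)
_SHORTCUTS = {
    "a": ("model", "a"), "b": ("model", "b"), "h": ("model", "h"),
    "r": ("model", "r"), "K": ("model", "K"),
    "D": ("passage", "D"), "tgrow": ("passage", "tgrow"),
    "cycles": ("passage", "n_cycles"), "burn_in": ("passage", "burn_in_cycles"),
    "M": ("meta", "M"), "F": ("meta", "F"),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for one scenario run."""

    scenario: int = 2
    model: ModelParams = field(default_factory=ModelParams)
    passage: PassageParams = field(default_factory=PassageParams)
    meta: MetaPopParams = field(default_factory=MetaPopParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    n0_co: float = 0.5
    n0_ch: float = 0.5
    seed: int = 0
    out: str = "runs"
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ConfigError(f"scenario must be 1, 2 or 3, got {self.scenario}")

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "model": dataclasses.asdict(self.model),
            "passage": dataclasses.asdict(self.passage),
            "meta": dataclasses.asdict(self.meta),
            "solver": dataclasses.asdict(self.solver),
            "init": {"n_co": self.n0_co, "n_ch": self.n0_ch},
            "seed": self.seed,
            "out": self.out,
            "analysis": dict(self.analysis),
        }


def _build(cls, block: dict, known: set, name: str):
    unknown = set(block) - known
    for key in sorted(unknown):
        warnings.warn(f"ignoring unknown key {name}.{key}", stacklevel=3)
    kwargs = {k: v for k, v in block.items() if k in known}
    try:
        return cls(**kwargs)
    except ParameterError as exc:
        raise ConfigError(f"invalid {name} block: {exc}") from exc


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    blocks = {name: dict(raw.pop(name, {}) or {})
              for name in ("model", "passage", "meta", "solver", "init", "analysis")}
    scenario = raw.pop("scenario", 2)
    seed = raw.pop("seed", 0)
    out = raw.pop("out", "runs")
    for key in list(raw):
        if key in _SHORTCUTS:
            block, name = _SHORTCUTS[key]
            blocks[block].setdefault(name, raw.pop(key))
            # shared knobs apply to both engines
            if name in _META_KEYS:
                blocks["meta"].setdefault(name, blocks[block][name])
    for key in sorted(raw):
        warnings.warn(f"ignoring unknown key {key}", stacklevel=2)

    # short runs get a proportionate burn-in unless one was given explicitly
    for name in ("passage", "meta"):
        blk = blocks[name]
        if "n_cycles" in blk and "burn_in_cycles" not in blk:
            blk["burn_in_cycles"] = min(50, int(blk["n_cycles"]) // 2)

    blocks["meta"].setdefault("seed", seed)
    init = blocks["init"]
    return RunConfig(
        scenario=scenario,
        model=_build(ModelParams, blocks["model"], _MODEL_KEYS, "model"),
        passage=_build(PassageParams, blocks["passage"], _PASSAGE_KEYS, "passage"),
        meta=_build(MetaPopParams, blocks["meta"], _META_KEYS, "meta"),
        solver=_build(SolverSettings, blocks["solver"], _SOLVER_KEYS, "solver"),
        n0_co=float(init.get("n_co", 0.5)),
        n0_ch=float(init.get("n_ch", 0.5)),
        seed=int(seed),
        out=str(out),
        analysis=blocks["analysis"],
    )


def load_config(path) -> RunConfig:
    """Parse a YAML (or JSON, a YAML subset) file into a validated RunConfig."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
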