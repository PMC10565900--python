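"""CSV/JSON output helpers: tidy time series, long-format sweeps, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_timeseries", "write_sweep", "write_sidecar", "read_timeseries"]

TIMESERIES_COLUMNS = ["time", "N_co", "N_ch", "p_cheat"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_timeseries(df: pd.DataFrame, path) -> Path:
    """Write a tidy time-series CSV; an empty frame yields a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=TIMESERIES_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sweep(sweep, path) -> Path:
    """Write a sweep in long format: one row per (a, b, replicate, statistic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sweep.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def write_sidecar(path, params: dict, seed: int | None = None, **extra) -> Path:
    """JSON sidecar capturing everything needed to reproduce a run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "params": _jsonable(params),
        "seed": seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    payload.update(_jsonable(extra))
    path.write_text(json.dumps(payload, indent=2))
    return path
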