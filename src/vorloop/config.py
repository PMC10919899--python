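"""Run configuration, validation, and serialization helpers.

A RunConfig fully determines a pipeline run given the code version: the
master seed, time step, synthetic-data settings, regularization, the list
of feedback gains, and experiment toggles.  Configs round-trip through
YAML; results serialize to JSON plus delimited trace tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .basis import TemporalFilter, TimeAxis

__all__ = ["RunConfig", "load_config", "save_config", "filter_to_record",
           "filter_from_record", "trajectory_frame", "json_default"]


@dataclass
class RunConfig:
    seed: int = 0
    dt: float = 5e-4                       # s
    g_true: float = 0.2                    # generative feedback gain
    g_list: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 10))
    n_cells: int = 5
    n_trials: int = 10
    noiseless: bool = False
    maxiter_nonvisual: int = 100
    visual_maxfev: int = 0                 # 0 keeps the open-loop visual fit
    directions: tuple = ("increase",)
    exclude_12_5_hz: bool = True
    no_prediction_variant: bool = False
    blocked_modes: tuple = ()

    def validate(self) -> None:
        errs = []
        if self.dt <= 0:
            errs.append("dt must be positive")
        if not 0 <= self.g_true < 1:
            errs.append("g_true must lie in [0, 1)")
        if any(not 0 <= g <= 1 for g in self.g_list):
            errs.append("g_list entries must lie in [0, 1]")
        if self.n_trials < 1:
            errs.append("n_trials must be >= 1")
        if self.n_cells < 1:
            errs.append("n_cells must be >= 1")
        for d in self.directions:
            if d not in ("increase", "decrease"):
                errs.append(f"unknown learning direction: {d}")
        if errs:
            raise ValueError("invalid config: " + "; ".join(errs))

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=json_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for key in ("g_list", "directions", "blocked_modes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        json.loads(json.dumps(dataclasses.asdict(cfg), default=json_default)),
        sort_keys=True))


def json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def filter_to_record(f: TemporalFilter) -> dict:
    return {
        "pathway": f.pathway,
        "dt": f.axis.dt,
        "t_max": f.axis.t_max,
        "latency": f.latency,
        "units": f.units,
        "weights": None if f.weights is None else f.weights.tolist(),
        "kernel": f.kernel.tolist(),
    }


def filter_from_record(rec: dict) -> TemporalFilter:
    axis = TimeAxis(rec["dt"], rec["t_max"])
    return TemporalFilter(
        kernel=np.asarray(rec["kernel"], dtype=float), axis=axis,
        pathway=rec.get("pathway", ""),
        weights=(None if rec.get("weights") is None
                 else np.asarray(rec["weights"], dtype=float)),
        latency=rec.get("latency", 0.0), units=rec.get("units", ""))


def trajectory_frame(trajectories: dict) -> "pd.DataFrame":
    """Tidy table (time, condition, H, T, R, E, P) from named trajectories."""
    import pandas as pd

    frames = []
    for name, tr in trajectories.items():
        c = tr.condition
        frames.append(pd.DataFrame({
            "time": tr.t, "condition": name, "H": c.H,
            "T": c.T if c.lights else np.zeros(c.n),
            "R": tr.R, "E": tr.E, "P": tr.P,
            "S": c.S if c.S is not None else np.zeros(c.n)}))
    return pd.concat(frames, ignore_index=True)
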