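"""Tidy on-disk formats for trials, fit results and configuration.

Time series travel as delimited text with one row per sample:
``condition_id,repeat,time_s,value`` — human-diffable and free of binary
dependencies.  Fit results and run configuration are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .basis import GammaDiffParams
from .fitting import FitResult, TrialSeries
from .models import DNParams, LinearParams
from .stimulus import TimeGrid

__all__ = [
    "read_trials",
    "write_trials",
    "split_blanks",
    "RunConfig",
    "fit_result_to_json",
    "fit_result_from_json",
]

_COLUMNS = ["condition_id", "repeat", "time_s", "value"]
_DT_TOL = 1e-9


def write_trials(trials: Iterable[TrialSeries], path: str | Path) -> None:
    """Write trials in the tidy delimited format (full float precision)."""
    rows = []
    for tr in trials:
        for t, v in zip(tr.grid.times, tr.values):
            rows.append((tr.condition_id, tr.repeat_index, t, v))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trials(path: str | Path) -> list[TrialSeries]:
    """Read trials from the tidy format, validating grid consistency.

    Each (condition_id, repeat) group must have strictly increasing
    ``time_s`` with a constant step shared by every trial in the file;
    violations are rejected with the offending trial and line named.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    trials: list[TrialSeries] = []
    ref: tuple[float, int] | None = None  # (dt, n_samples)
    # preserve file order of first appearance
    df["_order"] = np.arange(len(df))
    for (cid, rep), grp in sorted(
        df.groupby(["condition_id", "repeat"], sort=False),
        key=lambda kv: kv[1]["_order"].iloc[0],
    ):
        t = grp["time_s"].to_numpy(dtype=float)
        line0 = int(grp["_order"].iloc[0]) + 2  # 1-based incl. header
        steps = np.diff(t)
        if t.size < 1 or (t.size > 1 and (steps <= 0).any()):
            raise ValueError(
                f"{path}: trial {cid!r}/{rep} near line {line0}: "
                "time_s must be strictly increasing"
            )
        dt = float(steps[0]) if t.size > 1 else None
        if dt is not None and np.abs(steps - dt).max() > _DT_TOL:
            k = int(np.argmax(np.abs(steps - dt)))
            raise ValueError(
                f"{path}: trial {cid!r}/{rep} near line {line0 + k + 1}: "
                f"non-uniform time step ({steps[k]:g} vs {dt:g})"
            )
        if ref is None:
            ref = (dt if dt is not None else 1.0, t.size)
        elif (dt is not None and abs(dt - ref[0]) > _DT_TOL) or t.size != ref[1]:
            raise ValueError(
                f"{path}: trial {cid!r}/{rep} near line {line0}: grid "
                f"({dt}, {t.size} samples) differs from first trial "
                f"({ref[0]}, {ref[1]} samples)"
            )
        grid = TimeGrid(ref[0], ref[1])
        trials.append(TrialSeries(str(cid), int(rep), grid, grp["value"].to_numpy(float)))
    if not trials:
        raise ValueError(f"{path}: no trials found")
    return trials


def split_blanks(
    trials: Iterable[TrialSeries], blank_id: str = "blank"
) -> tuple[list[TrialSeries], list[TrialSeries]]:
    """Route trials whose condition id marks a blank into a separate list."""
    stim, blank = [], []
    for tr in trials:
        (blank if tr.condition_id == blank_id else stim).append(tr)
    return stim, blank


@dataclass
class RunConfig:
    """Validated configuration shared by the pipeline stages."""

    preset: str = "vsdi"  # vsdi | gcamp
    dt: float | None = None
    n_samples: int | None = None
    n_fast: int = 8
    n_slow: int = 10
    shift_ms: float = 30.0
    tol: float = 1e-6
    n_restarts: int = 5
    n_boot: int = 50
    seed: int = 0
    window: tuple[float, float] | None = None
    noise_sd: float | None = None
    slow_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.preset not in ("vsdi", "gcamp"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_fast < 2 or self.n_slow < 2:
            raise ValueError("basis counts must be >= 2")
        if self.tol <= 0 or self.n_restarts < 1 or self.n_boot < 1:
            raise ValueError("tol, n_restarts and n_boot must be positive")

    def grid(self) -> TimeGrid:
        from .stimulus import GCAMP_GRID, VSDI_GRID

        base = VSDI_GRID if self.preset == "vsdi" else GCAMP_GRID
        if self.dt is not None or self.n_samples is not None:
            return TimeGrid(self.dt or base.dt, self.n_samples or base.n_samples)
        return base

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("window"), list):
            data["window"] = tuple(data["window"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _params_to_dict(params: object) -> dict:
    if isinstance(params, DNParams):
        return {
            "kind": "dn",
            "numerator_weights": params.numerator_weights.tolist(),
            "denom_gamma": asdict(params.denom_gamma),
            "sigma": params.sigma,
            "slow_weights_by_condition": {
                k: v.tolist() for k, v in params.slow_weights_by_condition.items()
            },
        }
    if isinstance(params, LinearParams):
        return {
            "kind": "linear",
            "fast_weights": params.fast_weights.tolist(),
            "slow_weights_by_condition": {
                k: v.tolist() for k, v in params.slow_weights_by_condition.items()
            },
        }
    if isinstance(params, dict):
        return {"kind": "per_condition", "items": {k: _params_to_dict(v) for k, v in params.items()}}
    raise TypeError(f"cannot serialize params of type {type(params)}")


def _params_from_dict(d: dict) -> object:
    kind = d["kind"]
    if kind == "dn":
        return DNParams(
            np.asarray(d["numerator_weights"]),
            GammaDiffParams(**d["denom_gamma"]),
            d["sigma"],
            {k: np.asarray(v) for k, v in d["slow_weights_by_condition"].items()},
        )
    if kind == "linear":
        return LinearParams(
            np.asarray(d["fast_weights"]),
            {k: np.asarray(v) for k, v in d["slow_weights_by_condition"].items()},
        )
    if kind == "per_condition":
        return {k: _params_from_dict(v) for k, v in d["items"].items()}
    raise ValueError(f"unknown params kind {kind!r}")


def fit_result_to_json(result: FitResult, seed: int | None = None) -> str:
    """Serialize a fit result (weights, Gamma params, sigma, loss, metadata)."""
    return json.dumps(
        {
            "params": _params_to_dict(result.params),
            "loss": result.loss,
            "n_iterations": result.n_iterations,
            "converged": result.converged,
            "conditioning_warnings": result.conditioning_warnings,
            "loss_history": result.loss_history,
            "seed": seed,
        },
        indent=1,
    )


def fit_result_from_json(text: str) -> FitResult:
    d = json.loads(text)
    return FitResult(
        _params_from_dict(d["params"]),
        d["loss"],
        d["n_iterations"],
        d["converged"],
        d["conditioning_warnings"],
        d["loss_history"],
    )
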