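"""Temporal stimulus conditions and their discretization.

The experimental design probes temporal summation in V1 with twelve
conditions: six single pulses of a static pattern whose duration doubles
from 20 to 640 ms, and six double pulses (two 160 ms presentations of the
same pattern) whose inter-stimulus interval (ISI) doubles from 20 to
640 ms.  A condition is rendered as a binary-in-time contrast waveform
``s(t)`` on a uniform sampling grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "StimulusCondition",
    "StimulusVector",
    "VSDI_GRID",
    "GCAMP_GRID",
    "SINGLE_PULSE_DURATIONS_MS",
    "DOUBLE_PULSE_ISIS_MS",
    "PULSE_MS",
    "make_condition_set",
    "render",
    "required_oversample",
    "total_on_time",
    "conditions_to_json",
    "conditions_from_json",
]

#: Single-pulse durations and double-pulse ISIs (ms); each doubles the last.
SINGLE_PULSE_DURATIONS_MS = (20.0, 40.0, 80.0, 160.0, 320.0, 640.0)
DOUBLE_PULSE_ISIS_MS = (20.0, 40.0, 80.0, 160.0, 320.0, 640.0)
#: Pulse length in the double-pulse conditions (ms).
PULSE_MS = 160.0

_TOL_S = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid for one trial.

    Sample ``k`` covers the interval ``[k*dt, (k+1)*dt)``; the stimulus is
    aligned so its onset falls on ``onset_index`` (default 0, matching
    time courses whose onset latency has been removed in preprocessing).
    """

    dt: float
    n_samples: int
    onset_index: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not 0 <= self.onset_index < self.n_samples:
            raise ValueError(
                f"onset_index {self.onset_index} outside [0, {self.n_samples})"
            )

    @property
    def duration_s(self) -> float:
        """Total trial duration in seconds."""
        return self.dt * self.n_samples

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt


#: 100 Hz grid covering a 1.2 s trial (121 samples including t = 0).
VSDI_GRID = TimeGrid(dt=0.010, n_samples=121)
#: 20 Hz grid covering a 1.35 s trial (28 samples including t = 0).
GCAMP_GRID = TimeGrid(dt=0.050, n_samples=28)


@dataclass(frozen=True)
class StimulusCondition:
    """One temporal condition: one or two pulses at a given contrast."""

    condition_id: str
    pulse_durations_ms: tuple[float, ...]
    isi_ms: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        durs = tuple(float(d) for d in self.pulse_durations_ms)
        object.__setattr__(self, "pulse_durations_ms", durs)
        if len(durs) not in (1, 2):
            raise ValueError("a condition has one or two pulses")
        if any(d <= 0 for d in durs):
            raise ValueError(f"pulse durations must be positive: {durs}")
        if len(durs) == 1 and self.isi_ms != 0:
            raise ValueError("single-pulse conditions carry no ISI")
        if self.isi_ms < 0:
            raise ValueError(f"ISI must be nonnegative, got {self.isi_ms}")
        if not 0 <= self.contrast <= 1:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")

    @property
    def is_double(self) -> bool:
        return len(self.pulse_durations_ms) == 2


@dataclass(frozen=True)
class StimulusVector:
    """A condition rendered as ``s(t)`` on a grid."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_samples,):
            raise ValueError(
                f"values length {vals.shape} does not match grid "
                f"({self.grid.n_samples} samples)"
            )
        if np.any(vals < 0):
            raise ValueError("stimulus values must be nonnegative")
        object.__setattr__(self, "values", vals)


def make_condition_set(contrast: float = 1.0) -> list[StimulusCondition]:
    """Enumerate the twelve temporal conditions of the design.

    Six single-pulse durations (20–640 ms, doubling) followed by six
    double-pulse ISIs (20–640 ms, doubling) with 160 ms pulses.  Note the
    320 ms single pulse is the ISI-0 limit of the double-pulse family.
    """
    conds = [
        StimulusCondition(f"dur-{int(d)}", (d,), contrast=contrast)
        for d in SINGLE_PULSE_DURATIONS_MS
    ]
    conds += [
        StimulusCondition(f"isi-{int(isi)}", (PULSE_MS, PULSE_MS), isi, contrast)
        for isi in DOUBLE_PULSE_ISIS_MS
    ]
    return conds


def _n_on(duration_ms: float, dt: float) -> int:
    n = duration_ms / 1000.0 / dt
    n_round = round(n)
    if abs(n - n_round) * dt > _TOL_S:
        raise ValueError(
            f"duration {duration_ms} ms is not a multiple of dt = {dt * 1e3:g} ms"
        )
    return n_round


def render(
    cond: StimulusCondition, grid: TimeGrid, oversample: int = 1
) -> StimulusVector:
    """Discretize a condition as a contrast waveform on ``grid``.

    Each pulse duration and the ISI must be integer multiples of ``dt``.
    With ``oversample > 1`` the condition is rendered on a ``dt/oversample``
    grid and box-averaged down, which represents durations finer than ``dt``
    (e.g. 20 ms pulses on a 50 ms calcium-imaging grid) as fractional
    contrast over the covering samples.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    if oversample > 1:
        fine = TimeGrid(
            grid.dt / oversample,
            grid.n_samples * oversample,
            grid.onset_index * oversample,
        )
        v = render(cond, fine).values.reshape(grid.n_samples, oversample).mean(axis=1)
        return StimulusVector(grid, v)

    values = np.zeros(grid.n_samples)
    k = grid.onset_index
    for i, dur in enumerate(cond.pulse_durations_ms):
        if i > 0:
            k += _n_on(cond.isi_ms, grid.dt)
        n_on = _n_on(dur, grid.dt)
        if k + n_on > grid.n_samples:
            raise ValueError(
                f"condition {cond.condition_id!r} extends past the trial end "
                f"({grid.n_samples} samples)"
            )
        values[k : k + n_on] = cond.contrast
        k += n_on
    return StimulusVector(grid, values)


def required_oversample(cond: StimulusCondition, grid: TimeGrid, max_factor: int = 64) -> int:
    """Smallest oversampling factor that renders a condition on ``grid``.

    1 when every duration and ISI is a multiple of ``dt`` (the usual case);
    larger when e.g. a 20 ms pulse must be represented on a 50 ms calcium-
    imaging grid by rendering finer and box-averaging down.
    """
    durations = list(cond.pulse_durations_ms) + ([cond.isi_ms] if cond.is_double else [])
    for m in range(1, max_factor + 1):
        fine_dt = grid.dt / m
        if all(
            abs(d / 1000.0 / fine_dt - round(d / 1000.0 / fine_dt)) * fine_dt <= _TOL_S
            for d in durations
        ):
            return m
    raise ValueError(
        f"condition {cond.condition_id!r} not representable on dt = "
        f"{grid.dt * 1e3:g} ms within oversampling {max_factor}"
    )


def total_on_time(cond: StimulusCondition) -> float:
    """Total stimulus-on time in seconds (pulse durations summed, ISI excluded)."""
    return sum(cond.pulse_durations_ms) / 1000.0


def conditions_to_json(conds: list[StimulusCondition]) -> str:
    return json.dumps(
        [
            {
                "condition_id": c.condition_id,
                "pulse_durations_ms": list(c.pulse_durations_ms),
                "isi_ms": c.isi_ms,
                "contrast": c.contrast,
            }
            for c in conds
        ],
        indent=1,
    )


def conditions_from_json(text: str) -> list[StimulusCondition]:
    return [
        StimulusCondition(
            d["condition_id"],
            tuple(d["pulse_durations_ms"]),
            d.get("isi_ms", 0.0),
            d.get("contrast", 1.0),
        )
        for d in json.loads(text)
    ]
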