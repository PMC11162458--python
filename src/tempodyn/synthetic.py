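"""Trial-resolved synthetic datasets with the statistical structure of
widefield imaging recordings.

Each generated trial is the sum of four ingredients the analysis has to
disentangle:

* a stimulus-evoked *fast* component produced by a known linear or
  delayed-normalization system, delayed by a response-onset latency;
* a random *slow trend*, drawn per trial from broad raised-cosine bumps
  so its spectral content sits an order of magnitude below the fast
  filter's timescale;
* a deterministic *artifact* shared identically by every trial, stimulus
  or blank (emulating heartbeat-locked fluctuation and dye bleaching,
  which blank subtraction is designed to remove);
* i.i.d. Gaussian sample noise.

Blank trials carry everything but the fast component.  The canonical
ground-truth parameter set (:func:`default_dn_truth`) has a numerator
filter peaking at 50 ms with a small post-stimulus undershoot, and a
biphasic difference-of-Gammas denominator whose positive lobe peaks at
70 ms and negative lobe near 150 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .basis import (
    BasisSet,
    FilterShape,
    GCAMP_FAST_COVERAGE_S,
    GammaDiffParams,
    VSDI_FAST_COVERAGE_S,
    gamma_kernel,
    make_fast_basis,
)
from .fitting import TrialSeries
from .models import DNParams, LinearParams, convolve_causal, predict_dn
from .stimulus import StimulusCondition, TimeGrid, make_condition_set, render

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "default_dn_truth",
    "default_linear_truth",
    "default_fast_basis",
    "gcamp_dn_truth",
    "slow_trend_basis",
]

#: Conditions recorded with one fewer repeat in the reference sessions.
REDUCED_REPEAT_IDS = ("isi-320", "isi-640")
DEFAULT_LATENCY_MS = 30.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one synthetic dataset.

    ``noise_sd``, ``slow_amplitude`` and ``artifact_amplitude`` are in
    response units (the evoked component of the canonical truth peaks
    near 0.3).  ``response_latency_ms`` delays the evoked component
    relative to stimulus onset, emulating conduction delay; the
    preprocessing shift removes it again.
    """

    grid: TimeGrid
    generator_kind: Literal["linear", "dn"]
    truth_params: LinearParams | DNParams
    fast_basis: BasisSet
    n_repeats: int = 8
    noise_sd: float = 0.03
    slow_amplitude: float = 0.05
    artifact_amplitude: float = 0.1
    response_latency_ms: float = DEFAULT_LATENCY_MS
    reduced_repeat_ids: tuple[str, ...] = REDUCED_REPEAT_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for name in ("noise_sd", "slow_amplitude", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def default_fast_basis(grid: TimeGrid, n_funcs: int = 8) -> BasisSet:
    """Fast basis with modality-appropriate coverage for a given grid."""
    coverage = VSDI_FAST_COVERAGE_S if grid.dt <= 0.02 else GCAMP_FAST_COVERAGE_S
    return make_fast_basis(grid, n_funcs, coverage)


def _project(basis: BasisSet, target: np.ndarray) -> np.ndarray:
    w, *_ = np.linalg.lstsq(basis.matrix, target, rcond=None)
    return w


#: All ground-truth parameter sets are normalized so the largest evoked
#: peak across the twelve conditions is PEAK_RESPONSE response units; the
#: generator's default noise/trend/artifact amplitudes are stated against
#: this scale.
PEAK_RESPONSE = 0.3


def _normalize_peak(params: DNParams, fb: BasisSet) -> DNParams:
    peak = max(
        predict_dn(c, params, fb).fast.max() for c in make_condition_set()
    )
    return DNParams(
        params.numerator_weights * (PEAK_RESPONSE / peak),
        params.denom_gamma,
        params.sigma,
    )


def default_dn_truth(grid: TimeGrid, fast_basis: BasisSet | None = None) -> DNParams:
    """Canonical ground-truth DN parameters for recovery tests (VSDI-style).

    Numerator: a fast Gamma (time-to-peak 50 ms) minus a small, slower
    undershoot lobe, projected onto the fast basis.  Denominator: a
    biphasic difference of Gammas, positive lobe peaking at 70 ms,
    negative lobe near 150 ms, with a slightly positive net area so the
    drive ``sigma + s * f_n`` stays positive for every condition.
    """
    if grid.dt > 0.025:
        raise ValueError(
            f"grid dt = {grid.dt * 1e3:g} ms is too coarse to express the "
            "50 ms numerator peak"
        )
    fb = fast_basis if fast_basis is not None else default_fast_basis(grid)
    target = gamma_kernel(grid, 3.0, 0.025) - 0.22 * gamma_kernel(grid, 3.0, 0.06)
    weights = _project(fb, target)
    denom = _biphasic_denominator(
        w1=4.0, shape1=2.0, peak1_s=0.070, shape2=9.0, peak2_s=0.150
    )
    return _normalize_peak(DNParams(weights, denom, sigma=0.5), fb)


def _unit_peak_gamma_area(shape: float, scale: float) -> float:
    """Integral of the unit-peak Gamma kernel (analytic)."""
    from scipy.special import gamma as gamma_fn

    k = shape - 1.0
    return scale * gamma_fn(shape) / (k**k * np.exp(-k))


def _biphasic_denominator(
    w1: float, shape1: float, peak1_s: float, shape2: float, peak2_s: float,
    net_area_factor: float = 0.85,
) -> GammaDiffParams:
    """Difference-of-Gammas with lobes peaking at the given times.

    The negative kernel is weighted to ``net_area_factor`` of area balance:
    slightly net-positive, so suppression largely self-terminates (the
    band-pass character that preserves additivity) while ``sigma + s*f_n``
    stays positive for every condition.
    """
    scale1 = peak1_s / (shape1 - 1.0)
    scale2 = peak2_s / (shape2 - 1.0)
    w2 = net_area_factor * w1 * (
        _unit_peak_gamma_area(shape1, scale1) / _unit_peak_gamma_area(shape2, scale2)
    )
    return GammaDiffParams(w1, w2, shape1, scale1, shape2, scale2)


def gcamp_dn_truth(grid: TimeGrid, fast_basis: BasisSet | None = None) -> DNParams:
    """Slower ground-truth parameters matched to calcium-indicator dynamics."""
    fb = fast_basis if fast_basis is not None else default_fast_basis(grid)
    target = gamma_kernel(grid, 3.0, 0.05)
    denom = _biphasic_denominator(
        w1=3.0, shape1=2.0, peak1_s=0.100, shape2=9.0, peak2_s=0.300
    )
    return _normalize_peak(DNParams(_project(fb, target), denom, sigma=0.5), fb)


def default_linear_truth(
    grid: TimeGrid, fast_basis: BasisSet | None = None
) -> LinearParams:
    """Purely additive ground truth: the canonical numerator filter alone."""
    fb = fast_basis if fast_basis is not None else default_fast_basis(grid)
    target = gamma_kernel(grid, 3.0, 0.025) - 0.22 * gamma_kernel(grid, 3.0, 0.06)
    weights = _project(fb, target)
    filt = FilterShape(grid, weights @ fb.functions)
    peak = max(
        convolve_causal(render(c, grid), filt).max() for c in make_condition_set()
    )
    return LinearParams(weights * (PEAK_RESPONSE / peak))


def slow_trend_basis(grid: TimeGrid, n_bumps: int = 3) -> BasisSet:
    """Component curves used to draw random per-trial slow trends.

    The family emulates the slow variability of widefield recordings: a
    linear drift, a bleaching-like exponential decay (time constant about
    a third of the trial), and a few half-trial-wide raised-cosine bumps
    (down-weighted) for slow variability that neither a ramp nor a decay
    captures.  All components vary on timescales an order of magnitude
    slower than the evoked filter.  This is the generating family, distinct
    from the finer slow basis the fitters use to absorb such trends.
    """
    T = grid.duration_s
    t = grid.times
    fns = [t / T, np.exp(-t / (T / 3.0))]
    centers = np.linspace(0.0, T, n_bumps)
    width = T / 2.0
    for c in centers:
        arg = np.clip((t - c) * np.pi / (2.0 * width), -np.pi, np.pi)
        fns.append(0.4 * 0.5 * (1.0 + np.cos(arg)))
    return BasisSet(grid, np.stack(fns), coverage_s=T, kind="slow")


def _artifact(grid: TimeGrid, amplitude: float) -> np.ndarray:
    """Deterministic trial-locked structure: heartbeat-like oscillation + drift."""
    t = grid.times
    T = max(grid.duration_s, grid.dt)
    return amplitude * (0.6 * np.sin(2 * np.pi * 2.5 * t + 0.8) + 0.4 * t / T)


def _fast_component(
    spec: GeneratorSpec, cond: StimulusCondition
) -> np.ndarray:
    if spec.generator_kind == "dn":
        return predict_dn(cond, spec.truth_params, spec.fast_basis).fast
    filt = FilterShape(
        spec.grid, spec.truth_params.fast_weights @ spec.fast_basis.functions
    )
    return convolve_causal(render(cond, spec.grid), filt)


def generate_dataset(
    spec: GeneratorSpec,
    conditions: Sequence[StimulusCondition] | None = None,
) -> tuple[list[TrialSeries], list[TrialSeries], dict[str, np.ndarray]]:
    """Generate stimulus trials, blank trials, and the noiseless ground truth.

    Returns ``(trials, blanks, ground_truth)``.  ``ground_truth`` maps each
    condition id to its noiseless, onset-aligned evoked component — i.e.
    what preprocessing (blank subtraction + latency shift) should expose.
    Blank trials (two blank "conditions" worth, id ``blank``) contain the
    artifact, a slow trend and noise but no evoked component.  Fixing
    ``seed`` makes the dataset bit-identical.
    """
    if conditions is None:
        conditions = make_condition_set()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    n_lat = round(spec.response_latency_ms / 1000.0 / grid.dt)
    if abs(spec.response_latency_ms / 1000.0 / grid.dt - n_lat) > 1e-9:
        raise ValueError("response latency must be a multiple of dt")
    artifact = _artifact(grid, spec.artifact_amplitude)
    trend_basis = slow_trend_basis(grid)

    def draw_trend() -> np.ndarray:
        w = rng.normal(0.0, 1.0, trend_basis.n_funcs)
        return spec.slow_amplitude * (w @ trend_basis.functions)

    trials: list[TrialSeries] = []
    ground_truth: dict[str, np.ndarray] = {}
    for cond in conditions:
        fast = _fast_component(spec, cond)
        ground_truth[cond.condition_id] = fast
        delayed = np.concatenate([np.zeros(n_lat), fast[: grid.n_samples - n_lat]])
        n_rep = spec.n_repeats - (
            1 if cond.condition_id in spec.reduced_repeat_ids and spec.n_repeats > 1 else 0
        )
        for rep in range(n_rep):
            values = (
                delayed
                + draw_trend()
                + artifact
                + rng.normal(0.0, spec.noise_sd, grid.n_samples)
            )
            trials.append(TrialSeries(cond.condition_id, rep, grid, values))

    blanks = [
        TrialSeries(
            "blank",
            rep,
            grid,
            draw_trend() + artifact + rng.normal(0.0, spec.noise_sd, grid.n_samples),
        )
        for rep in range(2 * spec.n_repeats)
    ]
    return trials, blanks, ground_truth
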