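"""Preprocessing and parameter estimation.

Estimation follows the structure of the models:

* the two-component linear model is linear in all weights, so a single
  stacked least-squares solve fits one shared stimulus filter together
  with per-condition slow-trend weights (or independent per-condition
  solves for the filter-per-condition diagnostic);
* the delayed-normalization model is fit by alternating coordinate
  descent — batch A ({numerator weights, difference-of-Gammas
  denominator, sigma}, shared across conditions) by bounded nonlinear
  least squares, batch B (per-condition slow weights) in closed form —
  so the loss is non-increasing by construction;
* two simpler trend-extraction models (Gamma-filter boxcar plus a linear
  or exponential trend) serve as robustness checks on how the evoked
  component is separated from the slow drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import optimize

from .basis import (
    BasisSet,
    FilterShape,
    GammaDiffParams,
    gamma_diff_filter,
    gamma_kernel,
)
from .models import Components, DNParams, LinearParams, convolve_causal, predict_dn
from .stimulus import StimulusCondition, StimulusVector, TimeGrid, render

__all__ = [
    "TrialSeries",
    "FitResult",
    "AltModelParams",
    "preprocess",
    "average_trials",
    "fit_linear",
    "fit_dn",
    "fit_alt_model",
    "alt_model_components",
    "crossval_loco",
    "bootstrap_mean",
    "choose_basis_counts",
]

SIGMA_FLOOR = 1e-6
DEFAULT_SHIFT_MS = 30.0


@dataclass(frozen=True)
class TrialSeries:
    """One trial's sampled response time course."""

    condition_id: str
    repeat_index: int
    grid: TimeGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_samples,):
            raise ValueError(
                f"trial {self.condition_id!r}/{self.repeat_index}: length "
                f"{vals.size} != grid n_samples {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"trial {self.condition_id!r}/{self.repeat_index}: non-finite values"
            )
        object.__setattr__(self, "values", vals)


@dataclass
class FitResult:
    """Outcome of a model fit.

    ``params`` is a :class:`LinearParams`, :class:`DNParams`, or — for the
    filter-per-condition linear diagnostic — a mapping from condition id
    to :class:`LinearParams`.
    """

    params: object
    loss: float
    n_iterations: int = 1
    converged: bool = True
    conditioning_warnings: list[str] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)


def preprocess(
    trials: Iterable[TrialSeries],
    blanks: Iterable[TrialSeries],
    shift_ms: float = DEFAULT_SHIFT_MS,
) -> list[TrialSeries]:
    """Blank subtraction, onset-latency shift, and first-sample zeroing.

    The mean blank time course removes stimulus-independent structure
    shared by every trial (heartbeat artifact, dye bleaching).  Each trial
    is then advanced by ``shift_ms`` (zero-padding the tail) so response
    onsets align with stimulus onsets, and its first sample is subtracted
    so every time course starts at exactly 0.
    """
    blanks = list(blanks)
    trials = list(trials)
    if not blanks:
        raise ValueError("at least one blank trial is required")
    grid = blanks[0].grid
    n_shift_f = shift_ms / 1000.0 / grid.dt
    n_shift = round(n_shift_f)
    if abs(n_shift_f - n_shift) > 1e-9:
        raise ValueError(
            f"shift {shift_ms} ms is not a multiple of dt = {grid.dt * 1e3:g} ms"
        )
    blank_mean = np.mean([b.values for b in blanks], axis=0)
    out = []
    for tr in trials:
        if tr.grid != grid:
            raise ValueError(f"trial {tr.condition_id!r} is on a different grid")
        v = tr.values - blank_mean
        if n_shift:
            v = np.concatenate([v[n_shift:], np.zeros(n_shift)])
        v = v - v[0]
        out.append(replace(tr, values=v))
    return out


def average_trials(trials: Iterable[TrialSeries]) -> dict[str, TrialSeries]:
    """Arithmetic mean time course per condition (repeat_index set to -1)."""
    groups: dict[str, list[TrialSeries]] = {}
    for tr in trials:
        groups.setdefault(tr.condition_id, []).append(tr)
    if not groups:
        raise ValueError("no trials to average")
    return {
        cid: TrialSeries(cid, -1, g[0].grid, np.mean([t.values for t in g], axis=0))
        for cid, g in groups.items()
    }


def bootstrap_mean(
    trials: Iterable[TrialSeries], n_boot: int = 50, seed: int = 0
) -> list[dict[str, TrialSeries]]:
    """Bootstrap the per-condition trial means.

    Repeats are resampled with replacement within each condition; the
    default of 50 resamples matches standard practice for standard-error
    bands on widefield trial averages.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[TrialSeries]] = {}
    for tr in trials:
        groups.setdefault(tr.condition_id, []).append(tr)
    out = []
    for _ in range(n_boot):
        boot: dict[str, TrialSeries] = {}
        for cid, g in groups.items():
            idx = rng.integers(0, len(g), size=len(g))
            boot[cid] = TrialSeries(
                cid, -1, g[0].grid, np.mean([g[i].values for i in idx], axis=0)
            )
        out.append(boot)
    return out


# ---------------------------------------------------------------------------
# design-matrix helpers

def _as_values(avg: Mapping[str, TrialSeries | np.ndarray], cid: str) -> np.ndarray:
    v = avg[cid]
    return v.values if isinstance(v, TrialSeries) else np.asarray(v, dtype=float)


def _conv_design(s: StimulusVector, fast: BasisSet) -> np.ndarray:
    """Columns = stimulus convolved with each fast basis function."""
    return np.stack(
        [convolve_causal(s, FilterShape(fast.grid, f)) for f in fast.functions]
    ).T


def _lstsq(design: np.ndarray, y: np.ndarray, label: str, warnings: list[str]):
    w, _, rank, sv = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.append(f"{label}: rank-deficient design (rank {rank} < {design.shape[1]})")
    return w


def fit_linear(
    avg: Mapping[str, TrialSeries | np.ndarray],
    conditions: Iterable[StimulusCondition],
    fast: BasisSet,
    slow: BasisSet,
    share_filter: bool = True,
) -> FitResult:
    """Closed-form least-squares fit of the two-component linear model.

    With ``share_filter`` a single stimulus filter is estimated jointly
    across all conditions (per-condition slow weights); without it each
    condition gets an independent filter — the linearity diagnostic, since
    a truly linear system yields the same filter for every condition.
    """
    conds = [c for c in conditions if c.condition_id in avg]
    if not conds:
        raise ValueError("no overlapping conditions between avg and condition list")
    G = slow.matrix
    n_fast, n_slow = fast.n_funcs, slow.n_funcs
    warnings: list[str] = []

    if share_filter:
        n = fast.grid.n_samples
        rows = []
        y = []
        for k, c in enumerate(conds):
            F = _conv_design(render(c, fast.grid), fast)
            block = np.zeros((n, n_fast + len(conds) * n_slow))
            block[:, :n_fast] = F
            block[:, n_fast + k * n_slow : n_fast + (k + 1) * n_slow] = G
            rows.append(block)
            y.append(_as_values(avg, c.condition_id))
        design = np.vstack(rows)
        yv = np.concatenate(y)
        w = _lstsq(design, yv, "shared linear fit", warnings)
        params = LinearParams(
            w[:n_fast],
            {
                c.condition_id: w[n_fast + k * n_slow : n_fast + (k + 1) * n_slow]
                for k, c in enumerate(conds)
            },
        )
        loss = float(np.sum((yv - design @ w) ** 2))
        return FitResult(params, loss, conditioning_warnings=warnings)

    per: dict[str, LinearParams] = {}
    loss = 0.0
    for c in conds:
        F = _conv_design(render(c, fast.grid), fast)
        design = np.hstack([F, G])
        yv = _as_values(avg, c.condition_id)
        w = _lstsq(design, yv, f"linear fit [{c.condition_id}]", warnings)
        per[c.condition_id] = LinearParams(w[:n_fast], {c.condition_id: w[n_fast:]})
        loss += float(np.sum((yv - design @ w) ** 2))
    return FitResult(per, loss, conditioning_warnings=warnings)


# ---------------------------------------------------------------------------
# delayed-normalization coordinate descent

def _dn_fast_curves(
    theta: np.ndarray,
    conv_designs: list[np.ndarray],
    stim_values: list[np.ndarray],
    grid: TimeGrid,
) -> tuple[list[np.ndarray], float]:
    """Fast components for every condition plus a denominator-positivity penalty."""
    n_fast = conv_designs[0].shape[1]
    u = theta[:n_fast]
    w1, w2, sh1, sh2, sc1, sc2, sigma = theta[n_fast:]
    f_n = w1 * gamma_kernel(grid, sh1, sc1) - w2 * gamma_kernel(grid, sh2, sc2)
    curves = []
    penalty = 0.0
    n = grid.n_samples
    for F, s in zip(conv_designs, stim_values):
        numerator = F @ u
        denom = sigma + np.convolve(s, f_n)[:n] * grid.dt
        floor = 0.05 * sigma
        viol = np.clip(floor - denom, 0.0, None)
        penalty += float(np.sum(viol**2))
        curves.append(numerator / np.maximum(denom, floor))
    return curves, penalty


def fit_dn(
    avg: Mapping[str, TrialSeries | np.ndarray],
    conditions: Iterable[StimulusCondition],
    fast: BasisSet,
    slow: BasisSet,
    init: DNParams | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_outer: int = 200,
) -> FitResult:
    """Alternating coordinate-descent fit of the DN model.

    Batch A ({numerator weights, denominator Gammas, sigma}; one set for
    all conditions) is refined by bounded trust-region least squares with
    the slow weights held fixed; batch B (per-condition slow weights) is
    then solved in closed form.  Iteration stops when the relative loss
    change drops below ``tol``.  Denominator positivity is enforced by a
    quadratic penalty during the search and checked on the result.

    Numerator weights initialize from the shared linear fit; the
    denominator (weights, shapes and scales of both Gamma kernels are all
    free) initializes as a biphasic filter with its positive lobe peaking
    near 70 ms and a narrower negative lobe near 150 ms, jittered across
    ``n_restarts`` seeded restarts to escape local minima.
    """
    conds = [c for c in conditions if c.condition_id in avg]
    if not conds:
        raise ValueError("no overlapping conditions between avg and condition list")
    grid = fast.grid
    conv_designs = [_conv_design(render(c, grid), fast) for c in conds]
    stim_values = [render(c, grid).values for c in conds]
    ys = [_as_values(avg, c.condition_id) for c in conds]
    G = slow.matrix
    n_fast, n_slow = fast.n_funcs, slow.n_funcs

    if init is None:
        lin = fit_linear(avg, conds, fast, slow, share_filter=True)
        u0 = np.asarray(lin.params.fast_weights, float)
        # positive lobe (shape-1)*scale ~ 70 ms, negative lobe ~ 150 ms
        base = np.concatenate([u0, [0.5, 0.25, 2.0, 8.0, 0.07, 0.15 / 7.0, 1.0]])
    else:
        g0 = init.denom_gamma
        base = np.concatenate(
            [
                init.numerator_weights,
                [g0.weight1, g0.weight2, g0.shape1, g0.shape2,
                 g0.scale1, g0.scale2, init.sigma],
            ]
        )

    lo = np.concatenate(
        [np.full(n_fast, -np.inf), [0, 0, 1.05, 1.05, 2e-3, 2e-3, SIGMA_FLOOR]]
    )
    hi = np.concatenate(
        [np.full(n_fast, np.inf), [np.inf, np.inf, 15.0, 15.0, 1.0, 1.0, np.inf]]
    )
    rng = np.random.default_rng(seed)

    def residuals(theta: np.ndarray, slow_comps: list[np.ndarray]) -> np.ndarray:
        curves, penalty = _dn_fast_curves(theta, conv_designs, stim_values, grid)
        res = [y - sc - c for y, sc, c in zip(ys, slow_comps, curves)]
        res.append(np.array([1e3 * np.sqrt(penalty)]))
        return np.concatenate(res)

    best: FitResult | None = None
    for restart in range(max(1, n_restarts)):
        theta = base.copy()
        if restart > 0:
            theta[n_fast:-1] *= rng.lognormal(0.0, 0.3, size=6)
            theta[-1] *= rng.lognormal(0.0, 0.3)
        theta = np.clip(theta, lo, hi)
        slow_comps = [np.zeros(grid.n_samples) for _ in conds]
        history: list[float] = []
        prev = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_outer + 1):
            sol = optimize.least_squares(
                residuals,
                theta,
                bounds=(lo, hi),
                args=(slow_comps,),
                method="trf",
                x_scale="jac",
                max_nfev=60 * (n_fast + 7),
            )
            theta = sol.x
            curves, _ = _dn_fast_curves(theta, conv_designs, stim_values, grid)
            slow_w = [np.linalg.lstsq(G, y - c, rcond=None)[0] for y, c in zip(ys, curves)]
            slow_comps = [G @ w for w in slow_w]
            loss = float(
                sum(np.sum((y - sc - c) ** 2) for y, sc, c in zip(ys, slow_comps, curves))
            )
            history.append(loss)
            if np.isfinite(prev) and prev - loss <= tol * max(prev, 1e-30):
                converged = True
                break
            prev = loss
        params = DNParams(
            theta[:n_fast],
            GammaDiffParams(
                theta[n_fast], theta[n_fast + 1], theta[n_fast + 2],
                theta[n_fast + 4], theta[n_fast + 3], theta[n_fast + 5],
            ),
            float(theta[n_fast + 6]),
            {c.condition_id: w for c, w in zip(conds, slow_w)},
        )
        result = FitResult(params, history[-1], n_iter, converged, loss_history=history)
        if best is None or result.loss < best.loss:
            best = result
    return best


# ---------------------------------------------------------------------------
# alternative trend-extraction models

@dataclass
class AltModelParams:
    """Parameters of the boxcar-plus-trend extraction models.

    ``per_condition`` maps each condition id to a dict with keys
    ``gain`` (filter amplitude), ``peak_s`` (Gamma filter time-to-peak),
    and the trend parameters: ``slope`` for ``linear_trend``;
    ``amp``, ``rate``, ``offset`` for ``exponential_trend``.
    """

    model_kind: Literal["linear_trend", "exponential_trend"]
    per_condition: dict[str, dict[str, float]]
    shared_filter: bool = False


def _alt_trend_design(
    kind: str, grid: TimeGrid, rate: float = 0.0
) -> np.ndarray:
    t = grid.times
    if kind == "linear_trend":
        return t[:, None]
    return np.stack([np.exp(-abs(rate) * t), np.ones_like(t)]).T


def _alt_fit_condition(
    y: np.ndarray, s: StimulusVector, kind: str, grid: TimeGrid, peak_s: float | None
) -> tuple[dict[str, float], float]:
    """Profile fit: linear params in closed form inside a derivative-free search."""

    def solve(peak: float, rate: float) -> tuple[np.ndarray, np.ndarray, float]:
        filt = FilterShape(grid, gamma_kernel(grid, 2.0, max(peak, 1e-3) / 1.0))
        col = convolve_causal(s, filt)
        design = np.hstack([col[:, None], _alt_trend_design(kind, grid, rate)])
        w, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ w) ** 2))
        return w, design, sse

    # peak of a shape-2 Gamma kernel sits at t = scale, so scale == peak_s
    if kind == "linear_trend":
        if peak_s is None:
            res = optimize.minimize_scalar(
                lambda p: solve(p, 0.0)[2], bounds=(5e-3, 0.3), method="bounded"
            )
            peak_s = float(res.x)
        w, _, sse = solve(peak_s, 0.0)
        return (
            {"gain": float(w[0]), "peak_s": peak_s, "slope": float(w[1])},
            sse,
        )

    # Decay rates are kept within genuinely-decaying territory (time constant
    # between ~2 trials and ~30 ms for a 1.2 s trial): as rate -> 0 the
    # exponential-plus-offset family degenerates into a ramp with unbounded
    # amplitude, which destabilizes the evoked/trend split.
    rate_lo, rate_hi = 0.5 / grid.duration_s, 40.0

    def obj(x: np.ndarray) -> float:
        p = peak_s if peak_s is not None else x[0]
        rate = np.clip(abs(x[-1]), rate_lo, rate_hi)
        return solve(p, rate)[2]

    best = None
    for r0 in (1.0, 5.0, 15.0):
        x0 = np.array([0.05, r0]) if peak_s is None else np.array([r0])
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-12}
        )
        if best is None or res.fun < best.fun:
            best = res
    p = peak_s if peak_s is not None else float(best.x[0])
    rate = float(np.clip(abs(best.x[-1]), rate_lo, rate_hi))
    w, _, sse = solve(p, rate)
    return (
        {
            "gain": float(w[0]),
            "peak_s": p,
            "amp": float(w[1]),
            "rate": rate,
            "offset": float(w[2]),
        },
        sse,
    )


def fit_alt_model(
    avg: Mapping[str, TrialSeries | np.ndarray],
    conditions: Iterable[StimulusCondition],
    kind: Literal["linear_trend", "exponential_trend"],
    grid: TimeGrid,
    share_filter: bool = False,
) -> AltModelParams:
    """Fit a Gamma-filter boxcar model with a linear or exponential trend.

    Per condition (default) the filter's time-to-peak is free for each
    condition; with ``share_filter`` one time-to-peak is profiled jointly
    across conditions, with the remaining parameters per condition.
    """
    conds = [c for c in conditions if c.condition_id in avg]
    if not conds:
        raise ValueError("no overlapping conditions between avg and condition list")
    stims = {c.condition_id: render(c, grid) for c in conds}
    ys = {c.condition_id: _as_values(avg, c.condition_id) for c in conds}

    if share_filter:
        def total_sse(peak: float) -> float:
            return sum(
                _alt_fit_condition(ys[cid], stims[cid], kind, grid, peak)[1]
                for cid in stims
            )

        res = optimize.minimize_scalar(total_sse, bounds=(5e-3, 0.3), method="bounded")
        peak = float(res.x)
        per = {
            cid: _alt_fit_condition(ys[cid], stims[cid], kind, grid, peak)[0]
            for cid in stims
        }
    else:
        per = {
            cid: _alt_fit_condition(ys[cid], stims[cid], kind, grid, None)[0]
            for cid in stims
        }
    return AltModelParams(kind, per, shared_filter=share_filter)


def alt_model_components(
    params: AltModelParams, cond: StimulusCondition, grid: TimeGrid
) -> Components:
    """Fast/slow decomposition implied by a fitted alternative model."""
    p = params.per_condition[cond.condition_id]
    filt = FilterShape(grid, gamma_kernel(grid, 2.0, p["peak_s"]))
    fast = p["gain"] * convolve_causal(render(cond, grid), filt)
    t = grid.times
    if params.model_kind == "linear_trend":
        slow = p["slope"] * t
    else:
        slow = p["amp"] * np.exp(-p["rate"] * t) + p["offset"]
    return Components(fast, slow)


# ---------------------------------------------------------------------------
# model comparison

def _predict_fast(
    params: object,
    cond: StimulusCondition,
    fast: BasisSet,
) -> np.ndarray:
    if isinstance(params, DNParams):
        return predict_dn(cond, params, fast).fast
    filt = FilterShape(fast.grid, params.fast_weights @ fast.functions)
    return convolve_causal(render(cond, fast.grid), filt)


def crossval_loco(
    avg: Mapping[str, TrialSeries | np.ndarray],
    conditions: Iterable[StimulusCondition],
    model_kind: Literal["linear", "dn"],
    fast: BasisSet,
    slow: BasisSet,
    fast_only: bool = False,
    **fit_kwargs,
) -> dict[str, float]:
    """Leave-one-condition-out cross-validation, variance explained per condition.

    The model is fit to the remaining conditions; the held-out condition's
    evoked component is predicted from those parameters, and fresh slow
    weights are fit to the held-out residual (the trend is per-condition
    by construction, so it cannot be predicted across conditions).  With
    ``fast_only`` the score compares predicted evoked component against
    the data minus the refit trend instead of the full time course.
    """
    conds = [c for c in conditions if c.condition_id in avg]
    if len(conds) < 2:
        raise ValueError("leave-one-out needs at least 2 conditions")
    G = slow.matrix
    scores: dict[str, float] = {}
    for held in conds:
        rest = [c for c in conds if c is not held]
        if model_kind == "linear":
            fit = fit_linear(avg, rest, fast, slow, share_filter=True)
        else:
            fit = fit_dn(avg, rest, fast, slow, **fit_kwargs)
        y = _as_values(avg, held.condition_id)
        fast_pred = _predict_fast(fit.params, held, fast)
        v, *_ = np.linalg.lstsq(G, y - fast_pred, rcond=None)
        slow_fit = G @ v
        if fast_only:
            target, pred = y - slow_fit, fast_pred
        else:
            target, pred = y, fast_pred + slow_fit
        sst = float(np.sum((target - target.mean()) ** 2))
        sse = float(np.sum((target - pred) ** 2))
        scores[held.condition_id] = 1.0 - sse / sst if sst > 0 else 1.0
    return scores


def choose_basis_counts(
    avg: Mapping[str, TrialSeries | np.ndarray],
    conditions: Iterable[StimulusCondition],
    grid: TimeGrid,
    n_fast_candidates: Iterable[int] = (4, 6, 8, 10),
    n_slow_candidates: Iterable[int] = (6, 8, 10, 12),
    coverage_s: float = 0.260,
) -> tuple[int, int]:
    """Select fast/slow basis counts by leave-one-condition-out CV (linear model)."""
    from .basis import make_fast_basis, make_slow_basis

    conds = list(conditions)
    best, best_score = None, -np.inf
    for nf in n_fast_candidates:
        for ns in n_slow_candidates:
            fb = make_fast_basis(grid, nf, coverage_s)
            sb = make_slow_basis(grid, ns)
            score = float(
                np.mean(list(crossval_loco(avg, conds, "linear", fb, sb).values()))
            )
            if score > best_score:
                best, best_score = (nf, ns), score
    return best
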