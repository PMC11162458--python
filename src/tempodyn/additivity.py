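"""Temporal-additivity metrics and the two illustrative simulations.

The additivity test reduces each condition's evoked time course to one
number — its time integral — and asks how that number scales with total
stimulus-on time ``x``.  For an additive (linear) system, doubling the
stimulus duration doubles the integral and the inter-stimulus interval is
irrelevant, so the twelve condition sums fall on a line through the
origin.  A scaled power function ``a * x**c`` fit to the sums summarizes
departures: ``c`` near 1 is near-additive, ``c`` below 1 sub-additive.
The same one-number-per-condition metric applies to modalities too slow
for filter estimation (e.g. an amplitude per condition from fMRI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .basis import BasisSet, biphasic_index, FilterShape
from .models import DNParams, predict_dn
from .stimulus import (
    StimulusCondition,
    TimeGrid,
    make_condition_set,
    total_on_time,
)

__all__ = [
    "AdditivityResult",
    "summed_response",
    "additive_prediction",
    "subadditivity_exponent",
    "additivity_from_components",
    "simulate_contrast_homogeneity",
    "demo_mono_vs_biphasic",
    "sums_to_text",
    "align_scale",
]

#: Summation epoch (start_s, duration_s) used for field-potential-style
#: predictions: 1200 ms beginning 200 ms before stimulus onset.
ECOG_EPOCH = (-0.2, 1.2)


@dataclass(frozen=True)
class AdditivityResult:
    """Per-condition summed responses with the additive line and power fit."""

    per_condition_sum: dict[str, float]
    additive_prediction: dict[str, float]
    a: float
    c: float
    fit_sse: float


def summed_response(
    fast_component: np.ndarray,
    grid: TimeGrid,
    window: tuple[float, float] | None = None,
) -> float:
    """dt-weighted integral of an evoked component, optionally windowed.

    ``window`` is ``(start_s, duration_s)`` relative to stimulus onset;
    the default integrates whatever samples the curve carries (the whole
    trial, or the full convolution tail).  Samples before onset are only
    meaningful for epochs starting at negative times, where the curve is
    implicitly zero (causal system, zero pre-stimulus baseline).
    """
    curve = np.asarray(fast_component, dtype=float)
    if window is None:
        return float(np.sum(curve) * grid.dt)
    start_s, dur_s = window
    onset_t = grid.onset_index * grid.dt
    k0 = round((onset_t + start_s) / grid.dt)
    k1 = round((onset_t + start_s + dur_s) / grid.dt)
    if k1 <= k0:
        raise ValueError("summation window must have positive duration")
    if k1 > curve.size:
        raise ValueError(
            f"summation window [{start_s}, {start_s + dur_s}) s extends past the "
            f"sampled curve ({curve.size} samples)"
        )
    k0 = max(k0, 0)  # pre-trial part of the epoch contributes zero
    return float(np.sum(curve[k0:k1]) * grid.dt)


def additive_prediction(
    sums: Mapping[str, float],
    conditions: Sequence[StimulusCondition],
    anchor_condition: str = "dur-160",
) -> dict[str, float]:
    """Sums a perfectly additive system would give, anchored at one condition.

    Predicted sums are proportional to total stimulus-on time, scaled so
    the anchor condition's prediction equals its observed sum.
    """
    by_id = {c.condition_id: c for c in conditions}
    if anchor_condition not in by_id or anchor_condition not in sums:
        raise KeyError(f"anchor condition {anchor_condition!r} not available")
    x0 = total_on_time(by_id[anchor_condition])
    if x0 <= 0:
        raise ValueError("anchor condition has zero stimulus-on time")
    slope = sums[anchor_condition] / x0
    return {cid: slope * total_on_time(by_id[cid]) for cid in sums if cid in by_id}


def subadditivity_exponent(
    sums: Mapping[str, float], on_times: Mapping[str, float]
) -> tuple[float, float, float]:
    """Fit ``a * x**c`` to summed responses vs total stimulus-on time.

    Returns ``(a, c, fit_sse)``.  A log-log ordinary-least-squares slope
    seeds a nonlinear least-squares refinement of the untransformed SSE.
    ISI conditions contribute repeated points at the same ``x``.
    """
    cids = [cid for cid in sums if cid in on_times]
    if not cids:
        raise ValueError("no conditions shared between sums and on_times")
    y = np.array([sums[c] for c in cids], dtype=float)
    x = np.array([on_times[c] for c in cids], dtype=float)
    bad = [c for c, yy, xx in zip(cids, y, x) if yy <= 0 or xx <= 0]
    if bad:
        raise ValueError(f"power-law fit requires positive sums/on-times; offending: {bad}")
    # closed-form seed in log space
    lx, ly = np.log(x), np.log(y)
    c0, la0 = np.polyfit(lx, ly, 1)
    (a, c), _ = optimize.curve_fit(
        lambda xx, a, c: a * xx**c, x, y, p0=[np.exp(la0), c0], maxfev=10000
    )
    sse = float(np.sum((y - a * x**c) ** 2))
    return float(a), float(c), sse


def additivity_from_components(
    fast_by_condition: Mapping[str, np.ndarray],
    conditions: Sequence[StimulusCondition],
    grid: TimeGrid,
    window: tuple[float, float] | None = None,
    anchor_condition: str = "dur-160",
) -> AdditivityResult:
    """Run the full additivity pipeline on per-condition evoked components."""
    sums = {
        cid: summed_response(curve, grid, window)
        for cid, curve in fast_by_condition.items()
    }
    on_times = {c.condition_id: total_on_time(c) for c in conditions}
    a, c, sse = subadditivity_exponent(sums, on_times)
    pred = additive_prediction(sums, conditions, anchor_condition)
    return AdditivityResult(sums, pred, a, c, sse)


def align_scale(sums: Mapping[str, float], reference: Mapping[str, float]) -> float:
    """Least-squares scalar aligning one modality's sums to another's range."""
    cids = [c for c in sums if c in reference]
    if not cids:
        raise ValueError("no shared conditions to align")
    s = np.array([sums[c] for c in cids])
    r = np.array([reference[c] for c in cids])
    denom = float(s @ s)
    if denom == 0:
        raise ValueError("cannot align all-zero sums")
    return float(s @ r) / denom


def simulate_contrast_homogeneity(
    p: DNParams,
    fast: BasisSet,
    duration_ms: float = 200.0,
    contrasts: Sequence[float] | None = None,
    full_tail: bool = True,
) -> dict[float, tuple[np.ndarray, float]]:
    """DN response to one pulse at a ladder of contrasts (homogeneity test).

    Defaults: a 200 ms pulse at five contrasts halving from 100% down to
    6.25%.  A linear system would double its sum when contrast doubles;
    the DN model's denominator grows with contrast, so each doubling of
    contrast less than doubles the sum, and high-contrast responses turn
    biphasic (transient then suppression) while low-contrast ones stay
    monophasic.
    """
    if contrasts is None:
        contrasts = [1.0 / 2**k for k in range(5)]
    grid = fast.grid
    out: dict[float, tuple[np.ndarray, float]] = {}
    for con in contrasts:
        if not 0 < con <= 1:
            raise ValueError(f"contrast must lie in (0, 1], got {con}")
        cond = StimulusCondition(f"c{con:g}", (duration_ms,), contrast=con)
        comp = predict_dn(cond, p, fast, full_tail=full_tail)
        out[con] = (comp.fast, summed_response(comp.fast, grid))
    return out


def demo_mono_vs_biphasic(
    base: DNParams,
    fast: BasisSet,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Sub-additivity exponents under monophasic vs biphasic normalization.

    Runs the twelve-condition DN prediction twice with the same numerator
    and sigma: once with the denominator's second lobe removed (monophasic,
    low-pass — suppression persists over the filter's whole summation
    period) and once with the biphasic filter (band-pass — suppression
    terminates quickly).  Returns ``(c_mono, c_biphasic)``; persistent
    suppression accumulates with duration, so ``c_mono < c_biphasic``.
    """
    conds = make_condition_set()
    grid = fast.grid
    results = []
    for params in (base.with_monophasic_denominator(), base):
        curves = {
            c.condition_id: predict_dn(c, params, fast, full_tail=True).fast
            for c in conds
        }
        res = additivity_from_components(curves, conds, grid, window=window)
        results.append(res.c)
    return results[0], results[1]


def sums_to_text(
    sums: Mapping[str, float],
    conditions: Sequence[StimulusCondition],
    modality: str = "vsdi",
) -> str:
    """Summed-response table as delimited text."""
    by_id = {c.condition_id: c for c in conditions}
    lines = ["condition_id\ttotal_on_time_s\tsummed_response\tmodality"]
    for cid, val in sums.items():
        x = total_on_time(by_id[cid]) if cid in by_id else float("nan")
        lines.append(f"{cid}\t{x:.6g}\t{val:.10g}\t{modality}")
    return "\n".join(lines) + "\n"
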