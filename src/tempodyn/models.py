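"""Forward prediction for the two-component response models.

Both models decompose a trial time course into a stimulus-evoked *fast*
component and a stimulus-independent *slow* trend:

* linear:  ``r(t) = s(t) * f(t) + g(t)`` with ``f = sum_i u_i f_i`` built
  from the fast basis and ``g = sum_j v_j g_j`` from the slow basis;
* delayed normalization (DN):
  ``r(t) = [s(t) * f_l(t)] / [sigma + s(t) * f_n(t)] + g(t)``,
  where the normalization filter ``f_n`` lags the numerator filter ``f_l``.
  The delayed denominator leaves the earliest response linear, then
  divisively reduces gain and speeds dynamics — producing higher-gain,
  slower responses to brief stimuli, and transient-then-suppressed
  responses to sustained ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet, FilterShape, GammaDiffParams, gamma_diff_filter
from .stimulus import (
    StimulusCondition,
    StimulusVector,
    TimeGrid,
    render,
    required_oversample,
)

__all__ = [
    "LinearParams",
    "DNParams",
    "Components",
    "convolve_causal",
    "predict_linear",
    "predict_dn",
    "equivalent_percondition_filter",
]


@dataclass(frozen=True)
class LinearParams:
    """Fitted weights of the two-component linear model."""

    fast_weights: np.ndarray
    slow_weights_by_condition: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fast_weights", np.asarray(self.fast_weights, dtype=float)
        )
        object.__setattr__(
            self,
            "slow_weights_by_condition",
            {k: np.asarray(v, dtype=float) for k, v in self.slow_weights_by_condition.items()},
        )


@dataclass(frozen=True)
class DNParams:
    """Fitted parameters of the two-component delayed-normalization model.

    A single {numerator filter, denominator filter, sigma} triple serves
    all stimulus conditions; slow-trend weights are per condition.  The
    model output is invariant to jointly rescaling (numerator, sigma,
    denominator), so comparisons should use predicted components or the
    scale-free drive ratio rather than raw weights.
    """

    numerator_weights: np.ndarray
    denom_gamma: GammaDiffParams
    sigma: float
    slow_weights_by_condition: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        object.__setattr__(
            self, "numerator_weights", np.asarray(self.numerator_weights, dtype=float)
        )
        object.__setattr__(
            self,
            "slow_weights_by_condition",
            {k: np.asarray(v, dtype=float) for k, v in self.slow_weights_by_condition.items()},
        )

    def with_monophasic_denominator(self) -> "DNParams":
        return DNParams(
            self.numerator_weights,
            self.denom_gamma.without_second_lobe(),
            self.sigma,
            dict(self.slow_weights_by_condition),
        )


@dataclass(frozen=True)
class Components:
    """Predicted fast/slow decomposition of one condition's time course."""

    fast: np.ndarray
    slow: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.fast + self.slow


def convolve_causal(
    s: StimulusVector, f: FilterShape, full_tail: bool = False
) -> np.ndarray:
    """Causal discrete convolution of a stimulus with a filter, scaled by dt.

    Output sample ``k`` depends only on stimulus samples ``<= k``; history
    before the trial is zero.  By default the tail past the trial end is
    discarded (responses are analyzed within the trial window); with
    ``full_tail`` the whole length-``(2n - 1)`` convolution is returned,
    which is the right object for additivity theory checks that integrate
    the untruncated response.
    """
    if (s.grid.dt, s.grid.n_samples) != (f.grid.dt, f.grid.n_samples):
        raise ValueError("stimulus and filter must share the same grid")
    out = np.convolve(s.values, f.values) * s.grid.dt
    return out if full_tail else out[: s.grid.n_samples]


def _slow_component(
    cond_id: str,
    slow_weights: dict[str, np.ndarray],
    slow: BasisSet | None,
    n_out: int,
) -> np.ndarray:
    if slow is None or not slow_weights:
        return np.zeros(n_out)
    if cond_id not in slow_weights:
        raise KeyError(f"no slow weights for condition {cond_id!r}")
    g = slow_weights[cond_id] @ slow.functions
    if n_out > g.size:  # full-tail fast component: trend is zero past the trial
        g = np.concatenate([g, np.zeros(n_out - g.size)])
    return g


def predict_linear(
    cond: StimulusCondition,
    p: LinearParams,
    fast: BasisSet,
    slow: BasisSet | None = None,
    full_tail: bool = False,
) -> Components:
    """Predict the fast/slow components of the linear model for one condition."""
    s = render(cond, fast.grid, oversample=required_oversample(cond, fast.grid))
    filt = FilterShape(fast.grid, p.fast_weights @ fast.functions)
    fast_comp = convolve_causal(s, filt, full_tail=full_tail)
    slow_comp = _slow_component(
        cond.condition_id, p.slow_weights_by_condition, slow, fast_comp.size
    )
    return Components(fast_comp, slow_comp)


def predict_dn(
    cond: StimulusCondition,
    p: DNParams,
    fast: BasisSet,
    grid: TimeGrid | None = None,
    slow: BasisSet | None = None,
    full_tail: bool = False,
) -> Components:
    """Predict the fast/slow components of the DN model for one condition.

    Raises if ``sigma + s * f_n`` is not strictly positive at every sample —
    a biphasic denominator filter can drive it negative, which would leave
    the divisive model undefined rather than merely inaccurate.
    """
    grid = grid or fast.grid
    s = render(cond, grid, oversample=required_oversample(cond, grid))
    num_filt = FilterShape(grid, p.numerator_weights @ fast.functions)
    numerator = convolve_causal(s, num_filt, full_tail=full_tail)
    f_n = gamma_diff_filter(p.denom_gamma, grid)
    denom = p.sigma + convolve_causal(s, f_n, full_tail=full_tail)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        t_bad = bad[0] * grid.dt
        raise ValueError(
            f"DN denominator is nonpositive at t = {t_bad:.3f} s "
            f"(min {denom.min():.3g}); increase sigma or reduce the "
            "normalization drive"
        )
    fast_comp = numerator / denom
    slow_comp = _slow_component(
        cond.condition_id, p.slow_weights_by_condition, slow, fast_comp.size
    )
    return Components(fast_comp, slow_comp)


def equivalent_percondition_filter(
    fast_component: np.ndarray,
    s: StimulusVector,
    fast: BasisSet,
    n_funcs: int | None = None,
    ridge: float = 0.0,
    cond_threshold: float = 1e8,
) -> FilterShape:
    """Best single linear filter explaining one condition's evoked response.

    Least-squares deconvolution of the curve against the stimulus within
    the span of the fast basis.  For a linear system these per-condition
    filters coincide across conditions; systematic differences (gain and
    time-to-peak changes at brief durations) diagnose nonlinearity.

    Short pulses poorly constrain the late basis functions; rank-deficient
    or badly conditioned designs are solved minimum-norm and flagged in the
    returned filter's ``warnings`` (an optional ridge penalty is available
    for that pathology).
    """
    if not np.any(s.values):
        raise ValueError("cannot deconvolve against an all-zero stimulus")
    fns = fast.functions if n_funcs is None else fast.functions[:n_funcs]
    curve = np.asarray(fast_component, dtype=float)
    design = np.stack(
        [convolve_causal(s, FilterShape(fast.grid, f))[: curve.size] for f in fns]
    ).T
    warnings: list[str] = []
    if ridge > 0:
        n = fns.shape[0]
        aug_design = np.vstack([design, np.sqrt(ridge) * np.eye(n)])
        aug_curve = np.concatenate([curve, np.zeros(n)])
        w, _, rank, sv = np.linalg.lstsq(aug_design, aug_curve, rcond=None)
    else:
        w, _, rank, sv = np.linalg.lstsq(design, curve, rcond=None)
    if rank < fns.shape[0]:
        warnings.append(f"rank-deficient deconvolution design (rank {rank} < {fns.shape[0]})")
    elif sv[-1] > 0 and sv[0] / sv[-1] > cond_threshold:
        warnings.append(f"ill-conditioned deconvolution design (cond {sv[0] / sv[-1]:.2g})")
    return FilterShape(fast.grid, w @ fns, warnings=tuple(warnings))
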