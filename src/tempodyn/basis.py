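"""Temporal basis sets and impulse-response filters.

Two raised-cosine families parameterize the two components of a trial:

* a *fast* basis for the stimulus-evoked filter, log-warped in time so
  functions near the origin vary quickly and later ones slow down, covering
  up to 260 ms (VSDI) or 320 ms (GCaMP);
* a *slow* basis for the stimulus-independent trend, spanning the whole
  trial with the warp reversed — broad, slow functions early and denser,
  faster ones toward the trial end, where heartbeat-locked trial onsets
  leave the most residual variation.

The normalization (denominator) filter of the delayed-normalization model
is parameterized separately as a difference of two Gamma kernels, which
constrains it to a monophasic or biphasic impulse response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .stimulus import TimeGrid

__all__ = [
    "BasisSet",
    "GammaDiffParams",
    "FilterShape",
    "make_fast_basis",
    "make_slow_basis",
    "gamma_diff_filter",
    "gamma_kernel",
    "time_to_peak",
    "biphasic_index",
    "basis_to_text",
]

#: Default basis sizes; the experimental papers in this area select these by
#: cross-validation, for which :func:`tempodyn.fitting.crossval_loco` can be
#: reused with different counts.
DEFAULT_N_FAST = 8
DEFAULT_N_SLOW = 10
#: Fast-basis temporal coverage (s) for the two modality presets.
VSDI_FAST_COVERAGE_S = 0.260
GCAMP_FAST_COVERAGE_S = 0.320


@dataclass(frozen=True)
class BasisSet:
    """A family of sampled temporal basis functions.

    ``functions`` has shape ``(n_funcs, n_samples)``; ``kind`` records
    whether the set is convolved with the stimulus (``fast``) or added
    directly to the prediction (``slow``).
    """

    grid: TimeGrid
    functions: np.ndarray = field(repr=False)
    coverage_s: float = 0.0
    kind: Literal["fast", "slow"] = "fast"

    def __post_init__(self) -> None:
        fns = np.atleast_2d(np.asarray(self.functions, dtype=float))
        if fns.shape[0] < 1 or fns.shape[1] != self.grid.n_samples:
            raise ValueError(
                f"basis shape {fns.shape} incompatible with grid of "
                f"{self.grid.n_samples} samples"
            )
        if not np.all(np.isfinite(fns)):
            raise ValueError("basis functions must be finite")
        object.__setattr__(self, "functions", fns)

    @property
    def n_funcs(self) -> int:
        return self.functions.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Design-matrix view, shape ``(n_samples, n_funcs)``."""
        return self.functions.T


@dataclass(frozen=True)
class GammaDiffParams:
    """Difference-of-Gammas parameterization of the normalization filter.

    The filter is ``weight1 * g1(t) - weight2 * g2(t)`` where each ``g`` is
    a unit-peak Gamma kernel with the given shape and scale (seconds).
    ``weight2 = 0`` gives a monophasic (low-pass) filter; ``weight2 > 0``
    with a slower second kernel gives a biphasic (band-pass) one.
    """

    weight1: float
    weight2: float
    shape1: float
    scale1: float
    shape2: float
    scale2: float

    def __post_init__(self) -> None:
        if self.weight1 < 0 or self.weight2 < 0:
            raise ValueError("weights must be nonnegative")
        for name in ("shape1", "scale1", "shape2", "scale2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def without_second_lobe(self) -> "GammaDiffParams":
        """The monophasic variant (second kernel switched off)."""
        return GammaDiffParams(
            self.weight1, 0.0, self.shape1, self.scale1, self.shape2, self.scale2
        )


@dataclass(frozen=True)
class FilterShape:
    """A sampled impulse response on a grid."""

    grid: TimeGrid
    values: np.ndarray = field(repr=False)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_samples,):
            raise ValueError("filter length must equal grid n_samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("filter values must be finite")
        object.__setattr__(self, "values", vals)


def _raised_cosine(warped: np.ndarray, center: float, half_width: float) -> np.ndarray:
    # unit-peak cosine bump supported on |warped - center| <= 2*half_width
    arg = np.clip((warped - center) * np.pi / (2.0 * half_width), -np.pi, np.pi)
    return 0.5 * (1.0 + np.cos(arg))


def _log_cosine_family(
    warped: np.ndarray,
    phi_start: float,
    phi_end: float,
    n_funcs: int,
    tile_edges: bool = False,
) -> np.ndarray:
    """Raised cosines with centers equally spaced in warped time.

    By default spacing is chosen so the support of the last function ends
    exactly at ``phi_end`` (appropriate for causal filters, which vanish
    at the origin).  With ``tile_edges`` the first and last centers sit on
    the interval ends instead, so the family sums to ~1 across the whole
    range and can represent signals with nonzero boundary values
    (appropriate for an additive trend basis).  Each sampled function is
    rescaled to unit peak.
    """
    if tile_edges:
        delta = (phi_end - phi_start) / (n_funcs - 1)
        centers = phi_start + delta * np.arange(n_funcs)
    else:
        delta = (phi_end - phi_start) / (n_funcs + 2)
        centers = phi_start + delta * np.arange(1, n_funcs + 1)
    fns = np.stack([_raised_cosine(warped, c, delta) for c in centers])
    peaks = fns.max(axis=1)
    if np.any(peaks <= 0):
        raise ValueError("a basis function has no support on the grid")
    return fns / peaks[:, None]


def make_fast_basis(
    grid: TimeGrid, n_funcs: int = DEFAULT_N_FAST, coverage_s: float = VSDI_FAST_COVERAGE_S
) -> BasisSet:
    """Log-warped raised-cosine basis for the stimulus-evoked filter.

    Centers are equally spaced in ``log(t + dt)`` over ``(0, coverage_s]``,
    so early functions are narrow (fast) and later ones wide (slow).
    """
    if n_funcs < 2:
        raise ValueError("need at least 2 fast basis functions")
    if coverage_s > grid.duration_s + 1e-12:
        raise ValueError(
            f"coverage {coverage_s} s exceeds trial duration {grid.duration_s} s"
        )
    t0 = grid.dt
    warped = np.log(grid.times + t0)
    fns = _log_cosine_family(warped, np.log(t0), np.log(coverage_s + t0), n_funcs)
    fns[:, grid.times > coverage_s + 1e-12] = 0.0
    return BasisSet(grid, fns, coverage_s=coverage_s, kind="fast")


def make_slow_basis(grid: TimeGrid, n_funcs: int = DEFAULT_N_SLOW) -> BasisSet:
    """Raised-cosine basis for the slow trend, spanning the whole trial.

    The log warp is applied to reversed time, so the family starts with
    broad, slowly varying functions and ends with narrow, fast ones near
    the end of the trial.  Returned in order of peak time.
    """
    if n_funcs < 2:
        raise ValueError("need at least 2 slow basis functions")
    t0 = grid.dt
    t_max = grid.times[-1] if grid.n_samples > 1 else grid.dt
    warped = np.log((t_max - grid.times) + t0)
    fns = _log_cosine_family(
        warped, np.log(t0), np.log(t_max + t0), n_funcs, tile_edges=True
    )
    fns = fns[np.argsort(np.argmax(fns, axis=1))]  # early (broad) first
    return BasisSet(grid, fns, coverage_s=grid.duration_s, kind="slow")


def gamma_kernel(grid: TimeGrid, shape: float, scale: float) -> np.ndarray:
    """Unit-peak Gamma-shaped kernel ``(t/scale)^(shape-1) exp(-t/scale)``.

    Normalized so its continuous-time maximum (at ``t = (shape-1)*scale``)
    is 1, keeping multiplying weights interpretable as amplitudes.
    Requires ``shape >= 1`` (below 1 the kernel diverges at 0 and has no
    finite peak to normalize by).
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if shape < 1:
        raise ValueError("unit-peak normalization requires shape >= 1")
    t = grid.times
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(t > 0, (t / scale) ** (shape - 1.0) * np.exp(-t / scale), 0.0)
    if shape == 1:
        vals[t == 0] = 1.0
        peak = 1.0
    else:
        k = shape - 1.0
        peak = k**k * np.exp(-k)
    return vals / peak


def gamma_diff_filter(p: GammaDiffParams, grid: TimeGrid) -> FilterShape:
    """Evaluate the difference-of-Gammas normalization filter on a grid."""
    vals = p.weight1 * gamma_kernel(grid, p.shape1, p.scale1) - p.weight2 * gamma_kernel(
        grid, p.shape2, p.scale2
    )
    return FilterShape(grid, vals)


def time_to_peak(f: FilterShape) -> float:
    """Time (s) of the filter's global maximum; ties break earliest."""
    if not np.any(f.values > 0):
        raise ValueError("filter has no strictly positive value")
    return float(f.grid.times[int(np.argmax(f.values))])


def biphasic_index(f: FilterShape) -> float:
    """Fraction of total lobe area carried by the negative lobe.

    0 for a purely nonnegative (monophasic) filter; 0.5 for perfectly
    balanced positive and negative lobes.
    """
    pos = float(np.sum(np.clip(f.values, 0.0, None)))
    neg = float(-np.sum(np.clip(f.values, None, 0.0)))
    if pos + neg == 0:
        raise ValueError("biphasic index undefined for the zero filter")
    return neg / (pos + neg)


def basis_to_text(basis: BasisSet, labels: list[str] | None = None) -> str:
    """Delimited-text export: one column per function, header row of labels."""
    if labels is None:
        labels = [f"{basis.kind}_{i}" for i in range(basis.n_funcs)]
    if len(labels) != basis.n_funcs:
        raise ValueError("one label per basis function required")
    lines = ["time_s\t" + "\t".join(labels)]
    for k, t in enumerate(basis.grid.times):
        row = "\t".join(f"{v:.10g}" for v in basis.functions[:, k])
        lines.append(f"{t:.10g}\t{row}")
    return "\n".join(lines) + "\n"
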