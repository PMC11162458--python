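# Methods

This note documents the models, estimation procedures, numerical choices
and the synthetic-data design behind `tempodyn`, in the order a reader
would meet them in the pipeline.

## Signal model

A preprocessed trial time course is modelled as the sum of a
stimulus-evoked **fast** component and a stimulus-independent **slow**
trend.  Trials are sampled on a uniform grid (VSDI preset: dt = 10 ms,
1.2 s trial, 121 samples including t = 0; GCaMP preset: dt = 50 ms,
1.35 s trial, 28 samples), with sample *k* covering `[k·dt, (k+1)·dt)`
and stimulus onset at a configurable sample (default 0, appropriate after
the preprocessing latency shift).  Stimuli are binary-in-time contrast
waveforms; durations that do not divide dt are an error by default, and
are optionally represented on a coarse grid by rendering on a finer
internal grid and box-averaging down (used for the 20/40 ms conditions on
the 50 ms calcium-imaging grid; the rendered waveform then takes
fractional contrast values on the covering samples).

### Preprocessing

Three steps, in order: (1) the mean blank time course is subtracted from
every stimulus trial, removing structure shared identically by all trials
(heartbeat-locked fluctuation, dye bleaching); (2) each trial is advanced
by `shift_ms` (default 30 ms, an integer number of samples; the tail is
zero-padded), removing the conduction latency between stimulus and
response onset; (3) the first sample is subtracted from the whole time
course, so every trial starts at exactly 0.

### Basis sets

Both components are parameterized by raised-cosine families,
`b(φ) = (1 + cos(π·clip((φ − c)/2δ, −1, 1)))/2`, with centers equally
spaced by δ in warped time and each sampled function renormalized to unit
peak.

* **Fast basis** (default 8 functions): warp `φ(t) = log(t + t₀)` with
  `t₀ = dt` — the standard log warp; the exact constant is a design
  choice documented here.  Centers span `(0, coverage]` with the last
  support ending exactly at the coverage (260 ms VSDI / 320 ms GCaMP), so
  early functions are narrow (fast) and later ones wide.  The sampled
  family has full column rank, keeping least squares well posed.
* **Slow basis** (default 10 functions): the same construction on
  *reversed* time, so the family starts with broad, slowly varying
  functions and ends with narrow ones near the trial end (trial onsets
  are heartbeat-locked and the initial sample is pinned to 0, so residual
  variation accumulates late in the trial).  Unlike the fast basis, the
  first and last centers sit on the interval ends ("edge tiling"): the
  family sums to ≈1 everywhere and can represent trends with nonzero
  boundary values.  Without edge tiling, early slow trends fall partly
  outside the basis span and leak into the fast component (we measured
  72% out-of-span residual for a broad early trend, versus <1% with
  tiling).
* Basis counts are tunable; `choose_basis_counts` selects them by
  leave-one-condition-out cross-validation of the linear model.

### The models

* Linear: `r_l(t) = Σᵢ uᵢ [fᵢ * s](t) + Σⱼ vⱼ gⱼ(t)`.  One shared `u`
  across conditions with per-condition `v` (a single stacked
  least-squares solve), or an independent filter per condition for the
  linearity diagnostic.
* Delayed normalization:
  `r_n(t) = [s*f_l](t) / (σ + [s*f_n](t)) + Σⱼ vⱼ gⱼ(t)`, with `f_l` in
  the fast-basis span and `f_n = w₁·γ(t; k₁, θ₁) − w₂·γ(t; k₂, θ₂)` a
  difference of unit-peak Gamma kernels (peak normalization keeps the
  weights interpretable as amplitudes; the kernel peak sits at
  `(k−1)·θ`).  Convolution is causal with zero pre-trial history; by
  default predictions are truncated at the trial end, and a `full_tail`
  option retains the untruncated convolution for additivity theory
  checks, where discarding the tail would spuriously penalize long
  stimuli.

**Identifiability.** `r = N/(σ + D)` is invariant to scaling `(N, σ, D)`
jointly.  We keep all three free (the trust-region optimizer tolerates
the flat direction) and compare fits by predicted components, never raw
weights; the scale-free drive ratio `D/σ` is the meaningful strength.

**Division guard.** A biphasic `f_n` can drive `σ + s*f_n` negative after
stimulus offset.  Prediction *rejects* nonpositive denominators rather
than clipping (clipping would silently change the model class), naming
the first offending time; during fitting, violations are discouraged by a
quadratic penalty below a floor of 0.05 σ and the returned parameters are
checked.

## Estimation

* **Linear:** one minimum-norm least-squares solve.  Rank deficiency
  (e.g. a 20 ms pulse under-constraining the late basis functions) is
  reported via conditioning warnings, not silently regularized; an
  optional ridge exists for the deconvolution diagnostic.
* **DN (coordinate descent):** batch A — numerator weights, both Gamma
  weights, shapes and scales, and σ — by bounded trust-region nonlinear
  least squares with slow weights fixed; batch B — per-condition slow
  weights — in closed form.  The loss is non-increasing by construction
  (each batch cannot worsen it) and iteration stops at relative change
  < 1e-6 or 200 outer iterations.  Numerator weights initialize from the
  shared linear fit; the denominator initializes with its positive lobe
  peaking near 70 ms and a narrower negative lobe near 150 ms, and is
  jittered (log-normal, SD 0.3) across 5 seeded restarts; the best loss
  wins.  Bounds: weights ≥ 0, shapes in [1.05, 15], scales in
  [2 ms, 1 s], σ ≥ 1e-6.
* **Alternative trend extractions** (robustness checks): a Gamma-filter
  boxcar (shape 2, free time-to-peak) plus either a linear ramp `c₃·t`
  or an exponential `c₂·e^(−c₃t) + c₄`.  Linear parameters are profiled
  in closed form inside a derivative-free search (bounded Brent over the
  filter peak; Nelder–Mead with multistart over the decay rate).  The
  exponential family degenerates into an unbounded-amplitude ramp as the
  rate → 0, which destabilizes the evoked/trend split, so the rate is
  bounded to [0.5/trial, 40] s⁻¹.  An explicit gain multiplies the
  unit-peak filter in both variants.  `share_filter` profiles one
  time-to-peak jointly across conditions.
* **Cross-validation:** leave-one-condition-out.  The model is fit to the
  remaining conditions; the held-out evoked component is predicted from
  those parameters, fresh slow weights are fit to the held-out residual
  (the trend is per-condition by construction), and variance explained is
  `1 − SSE/SST` against the held-out time course (or, optionally, against
  the trend-removed time course; both give similar scores).
* **Bootstrap:** trial means resampled with replacement within condition,
  default 50 resamples, deterministic under a fixed seed.

## Additivity metrics

Each condition's evoked component is integrated (dt-weighted; default the
whole sampled curve, optionally a fixed epoch such as the 1200 ms window
beginning 200 ms before onset used for field-potential-style predictions).
The additive reference line is proportional to total stimulus-on time,
anchored at the 160 ms single pulse (the anchor is configurable; on-time
excludes the ISI, so all double-pulse conditions share x = 0.32 s).  The
sub-additivity exponent comes from fitting `a·x^c` by nonlinear least
squares seeded with the log–log OLS slope; ISI conditions enter as
repeated-x points.  Nonpositive sums are rejected by name — the power fit
is undefined there.  A least-squares scalar (`align_scale`) maps one
modality's sums onto another's range for cross-modality comparison, and a
table of one amplitude per condition (e.g. GLM betas from a slow
modality) can be fed directly to the same metric.

Two illustrative simulations ship with the package:

* **Contrast homogeneity:** a 200 ms pulse at five contrasts halving from
  100%.  The DN denominator grows with contrast, so each contrast
  doubling less than doubles the integrated response, and the response
  waveform transitions from monophasic (low contrast) to biphasic — an
  undershooting lobe — at high contrast.
* **Mono- vs biphasic normalization:** the twelve-condition prediction is
  run twice with the same numerator and σ, once with the denominator's
  negative lobe removed.  Monophasic (low-pass) suppression persists over
  the filter's whole summation period and accumulates with duration
  (c ≈ 0.78 for the canonical parameters); biphasic (band-pass)
  suppression self-terminates and restores near-additivity (c ≈ 1.07).

## Synthetic data

No public recordings accompany this analysis, so the generator is a
first-class module.  Each stimulus trial is the sum of:

1. the **evoked component** from a known linear or DN system, delayed by
   a 30 ms response latency (which the preprocessing shift removes);
2. a random per-trial **slow trend** — weights drawn i.i.d. N(0, 1)
   scaled by `slow_amplitude` on a family of {linear ramp, bleaching-like
   exponential decay (time constant ≈ trial/3), three down-weighted
   half-trial-wide cosine bumps}.  Per-trial (not per-condition) draws
   keep the trend stimulus-independent.  Its power above 4 Hz is < 0.1%
   of total (Hann-windowed, linearly detrended periodogram) — an order of
   magnitude below the evoked filter's timescale;
3. a deterministic **artifact** shared identically by every trial
   (2.5 Hz heartbeat-like sinusoid + linear drift), which blank
   subtraction removes exactly;
4. i.i.d. Gaussian **noise** per sample.

Blank trials (two blank conditions' worth) carry everything but the
evoked component.  Default 8 repeats per condition, with the last two ISI
conditions at 7 repeats as in the reference recordings.  Fixed seeds give
bit-identical datasets.

### Canonical ground truth

The canonical VSDI-style DN parameter set (`default_dn_truth`) is the
recovery-test fixture:

* numerator: γ(3, 25 ms) − 0.22·γ(3, 60 ms) projected onto the fast
  basis — time-to-peak 50 ms with a small, slower undershoot lobe
  (population membrane-potential responses undershoot after offset; the
  undershoot is also what lets the simulated response waveform itself
  turn biphasic at high contrast, since the divisive stage keeps a
  nonnegative numerator nonnegative);
* denominator: positive lobe γ(2, 35 ms·2) peaking at exactly 70 ms,
  negative lobe γ(9, 18.75 ms) peaking at exactly 150 ms (the narrow
  shape-9 kernel keeps the *difference* filter's trough near 150 ms
  rather than drifting later), weighted to 85% of area balance — slightly
  net-positive, so suppression largely self-terminates while
  `σ + s*f_n` stays positive for all twelve conditions including full
  convolution tails; w₁ = 4, σ = 0.5;
* the numerator is rescaled so the largest evoked peak across conditions
  is 0.3 response units — the scale convention against which the
  generator's default amplitudes (noise 0.03, trend 0.05, artifact 0.1)
  are stated.  Response units are arbitrary; every scale-free quantity
  (exponents, indices, correlations) is unaffected.

A slower variant (`gcamp_dn_truth`: numerator peak 100 ms, denominator
lobes 100/300 ms) serves the calcium-imaging preset.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis must cope with:
trend/evoked confounding, shared artifacts, trial noise, repeat
imbalance, onset latency.  It does **not** emulate spatial structure
(responses are pooled scalars), heartbeat-locked acquisition timing,
photobleaching chemistry, non-Gaussian or temporally correlated noise
(an AR(1) stress switch would be a straightforward extension), or
session-to-session nonstationarity.  Passing recovery tests on this
generator therefore shows the estimation machinery is correct and
well-conditioned under realistic amplitudes — not that the model is true
of any particular animal's data.

## Numerical choices and degenerate inputs

* Tolerances: DN coordinate descent stops at relative loss change 1e-6;
  σ is floored at 1e-6 response units; time-to-peak ties break to the
  earliest sample; the biphasic index is |negative lobe area| / total
  lobe area.
* Deconvolution of brief-pulse conditions is rank-deficient or
  ill-conditioned (condition number > 1e8 is flagged); solutions are
  minimum-norm with warnings attached to the returned filter rather than
  silently ridge-regularized, keeping the estimator plain least squares.
* Degenerate inputs are rejected with the offending value named:
  durations not divisible by dt, stimuli overrunning the trial, zero
  stimuli in deconvolution, nonpositive sums in the power fit,
  nonpositive DN denominators.
* All randomness (generator, restarts, bootstrap) flows through explicit
  integer seeds, default 0.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
experiment's native size — twelve conditions, 121-sample VSDI trials,
8 repeats, 5 fit restarts — which completes in seconds per fit on one
core; leave-one-condition-out CV of the DN model (12 refits, 1 restart
each, warm-started defaults) is the slowest stage at well under a minute.

## Known limitations

* The DN fit compares models in component space; raw parameter values are
  reported but not identified (see the scaling degeneracy above).
* The slow basis can in principle absorb slow parts of the evoked
  response for long stimuli; the shared-across-conditions fast parameters
  are what prevents this in practice, and the LOCO scores quantify it.
* The exponential-trend alternative model retains a small systematic
  extraction bias on strongly trended data even at its global optimum
  (verified by grid search); it is a robustness check, not a recommended
  extractor.
* The coarse-grid (GCaMP) preset represents 20/40 ms pulses as fractional
  contrast on 50 ms samples; filter estimates at those durations are
  correspondingly coarse.
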