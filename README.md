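# tempodyn

Temporal-dynamics modelling of widefield imaging responses from visual
cortex: two-component linear and delayed-normalization models, temporal
additivity metrics, and a synthetic-data generator for end-to-end testing.

## The scientific problem

Widefield voltage-sensitive dye imaging (VSDI) and widefield calcium
imaging (GCaMP) record the pooled response of a patch of cortex as one
scalar per time point per trial.  A central question about such signals is
how **additive** they are in time: if a stimulus is shown twice as long,
does the integrated response double?  If an image is shown twice with a
gap, does the gap matter?  Different recording modalities give strikingly
different answers — population imaging in V1 is near-additive while fMRI
and ECoG broadband amplitudes are strongly sub-additive — and a compact
model that captures both regimes makes the measurements comparable.

`tempodyn` implements that analysis for trial-resolved time courses
labelled by temporal condition: six single-pulse durations (20–640 ms,
doubling) and six double-pulse inter-stimulus intervals (20–640 ms,
doubling; 160 ms pulses), plus blank trials.

## Models

Every trial is decomposed into a stimulus-evoked *fast* component and a
stimulus-independent *slow* trend `g(t)`:

* **Two-component linear model**
  `r_l(t) = s(t) * f(t) + g(t)`,
  with `f = Σᵢ uᵢ fᵢ` built from log-warped raised-cosine basis functions
  (fast early, slow late; coverage 260 ms for VSDI, 320 ms for GCaMP) and
  `g = Σⱼ vⱼ gⱼ` from a slower raised-cosine family spanning the trial.
  All weights have a closed-form least-squares solution.

* **Two-component delayed normalization (DN) model**
  `r_n(t) = [s(t) * f_l(t)] / [σ + s(t) * f_n(t)] + g(t)`,
  where the normalization filter `f_n` — a difference of two Gamma
  kernels, monophasic (low-pass) or biphasic (band-pass) — lags the
  numerator filter `f_l`.  The delayed denominator produces higher gain
  and slower dynamics for brief stimuli, contrast saturation, and
  transient-then-suppressed responses.  One `{f_l, f_n, σ}` set serves
  all conditions; slow weights are per condition.  Fitting alternates
  bounded nonlinear least squares (DN parameters) with closed-form slow
  weights (coordinate descent).

Nonlinearity is diagnosed two ways: **per-condition equivalent filters**
(deconvolving each condition's mean response — a linear system yields the
same filter everywhere) and the **sub-additivity exponent**: a scaled
power function `a·x^c` fit to the per-condition integrated evoked
responses against total stimulus-on time `x`.  `c ≈ 1` is additive,
`c < 1` sub-additive.

## Worked example

Simulate a VSDI-style dataset from the canonical delayed-normalization
ground truth (8 repeats per condition, realistic trend/artifact/noise),
preprocess it, and run the full analysis:

```bash
tempodyn simulate --preset vsdi --seed 0 --out sim.csv
tempodyn preprocess --in sim.csv --out pre.csv
tempodyn report --in pre.csv --out report.json
```

which prints

```
wrote 94 trials + 16 blanks to sim.csv
preprocessed 94 trials -> pre.csv
report: DN loss 0.2213 (linear 0.5088); c = 1.049; c_mono = 0.808, c_biph = 1.050 -> report.json
```

Reading the numbers:

* the DN model fits the trial-averaged data about twice as well as the
  linear model (summed squared residual 0.22 vs 0.51), and its
  leave-one-condition-out variance explained is higher (0.965 vs 0.944
  mean across conditions in `report.json`) — the synthetic system really
  is normalized, and the fit detects it;
* the recovered denominator filter is biphasic (lobe-area index 0.36),
  matching the generator;
* the sub-additivity exponent of the extracted evoked components is
  `c = 1.05`: near-additive, as expected for band-pass (biphasic)
  normalization;
* re-running the twelve-condition prediction with the same parameters but
  a monophasic denominator gives `c_mono = 0.81` versus
  `c_biph = 1.05` — persistent (low-pass) suppression accumulates with
  stimulus duration, biphasic suppression self-terminates.  This single
  switch reproduces the qualitative gap between sub-additive
  (fMRI/ECoG-like) and near-additive (VSDI/GCaMP-like) dynamics;
* `report.json` also lists per-condition equivalent filters: gains are
  highest for the 20 and 40 ms conditions (≈5.1–5.2 vs ≈3.5–4.5 at longer
  durations) with time-to-peak at 50 ms — the signature of
  duration-dependent gain control.

The same stages are available as library calls (`tempodyn.fit_dn`,
`tempodyn.additivity_from_components`, …); see the module docstrings.

## Layout

| module | contents |
| --- | --- |
| `tempodyn.stimulus` | temporal conditions, sampling grids, `s(t)` rendering |
| `tempodyn.basis` | raised-cosine bases, difference-of-Gammas filters, filter summaries |
| `tempodyn.models` | forward prediction, causal convolution, equivalent-filter deconvolution |
| `tempodyn.fitting` | preprocessing, least-squares and coordinate-descent fits, alternative trend models, LOCO cross-validation, bootstrap |
| `tempodyn.additivity` | summed-response test, sub-additivity exponent, contrast and mono/biphasic simulations |
| `tempodyn.synthetic` | ground-truth parameter sets and the trial generator |
| `tempodyn.io`, `tempodyn.cli` | tidy text formats, JSON configs, the `tempodyn` command |

See `docs/methods.md` for modelling details, parameter choices and
limitations.
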