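# Methods

This note documents the models, the synthetic-data generators, and the
numerical choices behind `chromasupp`, in the order the pipeline runs.

## Stimuli

**Colorimetry.** Patch colors are Munsell chips: ten principal hues (5R
… 5RP) at Value 5/ and Chroma 2, 4 or 6, plus the neutral N 5/ for the
/0 condition.  The package embeds a 31-entry table of renotation
chromaticities adapted from illuminant C to D65, so the achromatic point
is exactly the D65 white (x, y) = (0.3127, 0.3290).  Absolute luminance
is a function of Value only, via the ASTM D1535 quintic luminance-factor
polynomial (white = 100) scaled by a configurable display white; the
helper `white_luminance_for_value5` pins Value 5 to the stated patch
luminances (16.0 cd/m² on the projector, 19.8 cd/m² on the CRT).

**Geometry.** Degrees ↔ pixels is a separable linear map from
`DisplayGeometry` (adequate at ≤ 16° eccentricity); pixel centers sit at
half-integer pixel coordinates.  Defaults: 1280 × 1024 px over
31.5° × 25.2° (imaging), 1280 × 959 px over 31.5° × 23.6°
(psychophysics; the vertical resolution is chosen for square pixels —
the CRT's pixel count is not stated).

**Patch pattern.** Ten 3.0° patches with 15-arcmin black fringes, centers
on a 12.4° ring at equal 36° polar steps; a whole-ring jitter of −12°,
0° or +12° and the hue arrangement are drawn once per seed (per block in
the experiment) and recorded in provenance.  The white fixation
rectangle is 0.3° (unstated in the source; configurable).

**Textures.** The background is 600 achromatic ellipses (3.3° × 1.8°,
random position/orientation) whose luminances are drawn from eight
levels.  Only the endpoints (0.23 and 30.24 cd/m²) are stated, so the
defaults are eight *equally spaced* levels; the stated realized mean
(15.4 cd/m²) is treated as descriptive.  600 ellipses leave a few
percent of the screen uncovered, so uncovered pixels are filled with
per-pixel level draws to keep every textured pixel on the eight-level
grid.  The psychophysics mask is an axis-aligned tiling of 1.5° squares
over eight levels spanning 0.32–30.37 cd/m².

**Scrambling.** The scrambled counterpart is a seeded permutation of
pixel locations (luminance and chromaticity planes move together), which
preserves the pixel-value multiset exactly.  `full` mode permutes the
whole screen except the protected fixation rectangle; `patches_only`
(the black-background control) permutes only pixels at the patch
locations and leaves the rest uniformly black (0.05 cd/m²).

**Grating.** L(x, y) = L̄ [1 + A·e^{−r/3.75°}·cos(2π·0.67·x + π)]:
vertical carrier, phase fixed so the screen center is a luminance trough
("negative contrast at the center"), decremental exponential contrast
envelope.  The stimulus is specified by its *spatially-maximum Michelson
contrast* — the Michelson contrast formed from the global luminance
extrema of the rendered image.  Because the envelope has already decayed
to e₁ = exp(−1/(2f·3.75)) at the first carrier peak, the raw modulation
A is calibrated in closed form, A = 2C / (1 + e₁ + C(1 − e₁)), so that
the measured quantity equals the nominal contrast C; at the default
resolution the rendered error is < 0.4 % relative (tested at C = 0.34,
0.50, 0.66).  The carrier orientation is not stated in the source;
vertical is the documented default.

## BOLD block-response model

The block-averaged response of one visual area, sampled at the 13 grid
times t_n = 0 … 30 s in 2.5 s steps, is modelled as two Gaussian pulses
— activation (center T₁, width α₁, intensity a₁ > 0) and undershoot
(T₂, α₂, a₂ < 0) — integrated over the 15 s window [t_n − 15, t_n] with
a Heaviside gate at stimulus onset, plus a linear drift b·t + d.  The
window integrals have the error-function closed form
α√(π/2)·[erf((hi−T)/α√2) − erf((lo−T)/α√2)], verified against
quadrature to ≤ 1e−8 relative over the full parameter box.

**Objective.** EV = Σ_conditions Σ_n ((R − ModelR)/ModelR)², a *relative*
squared error.  Model values with |ModelR| < ε are clamped to ±ε in the
denominator (ε = 1e−3 % signal change, configurable); clamp events are
counted in the fit diagnostics.  The relative objective means fits
degrade sharply when the response is weak — the synthetic control
cohort occasionally shows exactly the large-EV tail the weakest-area
data showed in the source study.

**Joint fit.** The four temporal parameters are shared across the four
Chroma conditions of one (subject, area); (a₁, a₂, b, d) are free per
condition under the sign constraints.  The optimizer is nested:

* outer — bounded Nelder–Mead over (T₁, T₂, α₁, α₂) with
  T₁ ∈ [2, 12] s, T₂ ∈ [8, 25] s, α ∈ [0.5, 8] s, the ordering T₁ < T₂
  enforced by penalty; five starts by default, the first at a canonical
  HRF (6, 16, 2.5, 4) and the rest drawn from the seeded RNG;
* inner — per-condition damped Gauss–Newton on the relative residuals
  with an analytic Jacobian and projection onto a₁ ≥ 1e−6,
  a₂ ≤ −1e−6, warm-started across outer iterations (a bounded
  trust-region least-squares solve is used for the final inner pass);
* polish — one joint L-BFGS-B refinement of all 20 parameters.

The fit is deterministic for fixed (data, config).  Noise-free synthetic
data are recovered to EV ≤ 1e−10 with all parameters within 0.01 %
relative; under the study's noise conditions (per-block σ = 5 % of the
peak, 54-block averaging) the temporal parameters are recovered with a
mean max-relative error of ~6 % over 20 seeded repetitions.  On single
noisy draws the undershoot width α₂ is only weakly identified: the
global optimum can sit 15–20 % from the truth while fitting the data
strictly better than the truth does, so recovery is assessed in
aggregate, not per draw.

**Peak and normalization.** The response measure is the maximum of the
fitted curve on a dense grid (0.01 s) over [0, 30] s, drift included by
default (the source used "the peak point of the fitted curve" without
stating whether drift was excluded; a pulses-only mode is provided).
Normalization subtracts the four-condition mean from each condition's
peak (so normalized values sum to zero per subject); a ratio-to-mean
mode is provided because the source describes the normalization both
ways.

## Psychometric analysis

Responses are "test seen as higher contrast" at nine test contrasts
equally spaced over 0.34–0.66 (the source states the range and nine
levels).  The first two of twelve sessions are discarded (learning
effect), leaving 10 trials per (condition, contrast) cell at the study
scale.  The psychometric function is the plain cumulative Gaussian
Φ((x − μ)/σ) with no lapse term, fitted by trialwise Bernoulli maximum
likelihood over (μ, log σ) with σ bounded to [1e−4, 1]; bound hits and
all-identical-response tables are flagged, not raised.  Least squares on
proportions is retained for comparison (agrees within 5 % on noise-free
tables).  σ is the luminance-sensitivity index (larger σ = shallower
slope = lower effective S/N of the luminance signal); 1/σ is exposed as
`sensitivity_index`, and the 75 % discrimination threshold is
μ + σ·Φ⁻¹(0.75).  At 200 trials/level the ML estimator is unbiased with
~5 % sampling SD, so recovery checks average five seeded replicates.
Observers whose mean σ across conditions exceeds 3× the cohort median
are excluded (the reported cohort dropped one observer at 0.35 against
0.05–0.12; the rule reproduces exactly that decision on the synthetic
cohort).

## Synthetic data

No raw data are deposited, so the generators define the study
conditions:

* **Schedule** — 18 runs × (1 dummy + 12 blocks), every condition 3×
  per run in seeded pseudorandom order → 54 blocks/condition, 216 total.
  One awareness task per block succeeds with probability 0.987 (the
  reported accuracy); a run with > 3 errors is excluded, removing 3
  blocks per condition.
* **BOLD** — per condition, the model curve plus Gaussian noise
  (optional AR(1)); per-block simulation averages the schedule's
  retained blocks, the default averaged mode adds the equivalent
  σ/√N noise directly.  Per-block σ defaults to 5 % of the cohort mean
  peak — chosen so the 54-block averages resemble the published example
  time courses (EV median ≈ 0.02).
* **Cohorts** — group means and variance components are anchored to the
  published group statistics: main arm mean V1 peak 3.14 % signal
  change, between-subject SD 0.69, condition offsets (+0.09, −0.08,
  −0.03, +0.02 for /0, /2, /4, /6 — the suppression ordering), and a
  subject × condition interaction SD of 0.10, which together land the
  ANOVA variance decomposition near the published table.  The control
  arm uses mean 1.69, near-zero chroma-ordered offsets, and interaction
  SD 0.19 (no significant effect).  The region analysis gives each
  subject one shared base amplitude for the inside/on-patch regions with
  a per-subject ratio jitter of SD 0.15 around target ratios 0.842
  (main) and 0.610 (control).
* **2AFC observers** — Bernoulli responses with
  P = (1 − λ)Φ((x − μ_c)/σ_c) + λ/2, λ = 0 by default; group-mean σ
  (0.080, 0.105, 0.068, 0.075) makes /2 selectively worst, per-subject
  lognormal scale SD 0.15, and the eleventh observer's σ inflated 4× to
  exercise the exclusion rule.

What the generators do *not* emulate: physiological noise structure
beyond AR(1), voxel-level spatial structure, retinotopic ROI definition,
inter-area correlations, response nonstationarity, or observer lapses
and learning beyond the discarded sessions.  Passing tests therefore
show that the analysis chain is correct and well-calibrated under its
own assumptions — not that those assumptions hold for real scanner data.

## Group statistics

The one-way repeated-measures ANOVA is computed directly from the
within-subject decomposition (SS_condition, SS_subject, SS_residual;
F = MS_cond/MS_resid) so the table carries the Subject row in the
published layout; no sphericity correction is applied by default
(Greenhouse–Geisser is available and flagged).  The decomposition
conserves total SS to 1e−9 relative and its null calibration is
0.050 ± 0.01 at α = 0.05 over 10⁴ simulated 13 × 4 tables.  Tukey HSD
uses q = |mean_i − mean_j| / √(MS_resid/n) with studentized-range tail
probabilities; tests verify them to 1e−6 against an independent
double-quadrature implementation of the distribution.  The main-vs-
control magnitude comparison defaults to Welch's t (the cohorts overlap
only partially); paired and pooled modes are available.  The inside/on
ratio is a plain quotient of condition-averaged magnitudes, not a test.

## Problem sizes and determinism

The default analysis scale is the study scale: 13 subjects × 4
conditions × 13 time points for each imaging arm, 11 observers × 12
sessions × 36 trials for psychophysics; recovery suites use 20 seeded
fit repetitions and 5 × 1800-trial observer replicates, and the null
calibration uses 10⁴ tables.  Every stochastic stage takes an explicit
seed; cohort and pipeline seeds are derived hierarchically from one
master seed (kept below 2³¹) and recorded in outputs, so pipeline
bundles are byte-identical across reruns of the same config.

## Known limitations

* The renotation chromaticities are embedded only for the 31 chips the
  stimuli need; other Munsell designations raise `UnsupportedChipError`.
* The EV objective is undefined at ModelR = 0; the ε-clamp is a
  documented regularisation, and fits to near-zero responses (weak
  areas) inherit the objective's instability.
* The psychometric model has no lapse parameter by design; data from
  lapsing observers will inflate σ estimates.
* The optimizer's outer search is derivative-free and bounded; pulses
  outside the bounds box (e.g. undershoot centers > 25 s) are not
  representable.
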