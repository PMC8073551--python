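# Methods

## The cosinor model

Expression of a clock gene sampled over one circadian cycle is modelled as
a single-component cosinor with fixed period τ (24 h by default):

    Y(t) = α·sin(2πt/τ) + β·cos(2πt/τ) + γ + ε,   ε ~ N(0, σ²)

Because the model is linear in (α, β, γ) it is fit by ordinary least
squares; no period estimation is attempted (sampling every 2 h over a
single cycle cannot resolve the period anyway). Replicates and independent
experiments are pooled as i.i.d. observations in one regression — no batch
term is fitted by default, although the generator can plant an additive
per-experiment offset to probe sensitivity to that assumption.

Derived parameters:

* **MESOR** γ — rhythm-adjusted mean, the intercept.
* **Amplitude** A = √(α² + β²) — half the peak-to-trough extent.
* **Acrophase** θ = atan2(−α, β), wrapped into (−2π, 0] — the unique angle
  with β = A·cosθ and α = −A·sinθ, so the fitted curve is
  γ + A·cos(2πt/τ + θ) and the peak sits at t = −θ·τ/2π. The atan2 form
  reproduces every branch of the classical per-quadrant arctangent
  correction and is unambiguous at the axes; the (−2π, 0] window is the
  standard cosinor reporting convention.

**Rhythmicity** is the zero-amplitude F-test: the cosinor fit against the
intercept-only fit,

    F = ((RSS₀ − RSS₁)/2) / (RSS₁/(n − 3)),  p from the exact F(2, n−3) tail.

Exact tails are used throughout. Fits need n ≥ 4 observations at ≥ 3
non-collinear time points; rank-deficient designs raise an error rather
than returning a pseudo-inverse fit.

## Differential rhythmicity

Two conditions are compared by stacking their observations with an
indicator g (0 = control, 1 = perturbed):

    Y = (α₁ + g·α₂)·X₁ + (β₁ + g·β₂)·X₂ + γ  (+ γ₂·g, optional)

The intercept is shared by default, which is the natural reading of the
stacked model; `shared_mesor=False` adds a condition-specific intercept
because unequal baselines otherwise leak into (α₂, β₂). With separate
intercepts the stacked fit factorizes exactly into the two per-condition
cosinor fits (a tested invariant).

Reported effects:

* amplitude change A₂ − A₁ and fold A₂/A₁, with
  A₁ = √(α₁² + β₁²), A₂ = √((α₁+α₂)² + (β₁+β₂)²);
* phase shift in hours, (θ₂ − θ₁)·τ/2π wrapped into (−τ/2, τ/2], with
  **positive = advance** (the perturbed culture peaks earlier). A planted
  advance of τ − h therefore reads as a delay of h — phase is circular and
  the fit cannot distinguish the two.

Significance:

* `p_differential_rhythmicity` — nested F-test of (α₂, β₂) = (0, 0),
  2 numerator df, n − 5 (or n − 6) denominator df;
* `p_amplitude`, `p_phase` — delta-method standard errors of A₂ − A₁ and
  θ₂ − θ₁ propagated through the OLS coefficient covariance, two-sided
  normal reference. The delta method is a large-n linearization; at A near
  zero the phase gradient blows up, so when either condition is essentially
  arrhythmic both parameter-level p-values fall back to the joint test.

Degenerate (zero-residual) fits are flagged and reported with p = 0 when a
non-zero effect is present and p = 1 when none is, rather than being
clipped silently.

**Multiple testing.** Benjamini–Hochberg step-up by default (Sidak
available). Families: all gene×condition rhythmicity p-values form one
family; differential p-values form one family per parameter type across
genes×pairs; endpoint comparisons are Sidak-corrected within each
gene×timepoint across the condition pairs tested there — the smallest
defensible family for a per-panel pairwise comparison. Family sizes and
methods are recorded in the output provenance.

## qPCR normalization

Efficiency-corrected (Pfaffl-style) relative quantification: per-gene
quantity Q = E^(−Cq) with amplification efficiency E ∈ (1, 2], normalized
by the geometric mean of the reference-gene quantities per sample, and
optionally re-scaled to a calibrator sample. Technical replicates are
averaged on the Cq scale first (conventional practice). With every E = 2
this reduces to the classic 2^(−ΔCq) against the reference geometric mean,
and adding a constant to every Cq of a sample (equal efficiencies) cancels
— per-sample loading invariance, kept as a test. Samples missing a
reference measurement are dropped with a warning; no inter-plate
calibration is modelled.

## Growth calibration and dosing

Within the exponential window (2–5 h after dilution) CFU/mL is regressed
on OD600 by ordinary least squares on the original scale — the calibration
is used as a ratio at a measured OD, so a log–log fit would only obscure
it. The intercept is retained by default with a zero-intercept (pure
ratio) option, since published descriptions of such calibrations are
ambiguous on this point. Rows outside the window never influence the fit.
Dosing: cfu_needed = MOI × n_cells, volume = cfu_needed / predicted
density; the default MOI of 0.005 bacteria per host cell is the gentle
inoculum used in hepatocyte co-culture work.

## The synthetic-data generator

The generator emulates the study design the estimators assume: samples
every 2 h over 24 h (optionally extended with 48/72 h endpoint samples),
two independent experiments treated as i.i.d. duplicates, a 24-h period,
cosine-shaped truth per gene with condition-specific amplitude scaling and
phase shifts (specified in hours, positive = advance), and additive
Gaussian noise on the relative-expression scale — Gaussian because the
model is fit by unweighted least squares on that scale. Default effect
sizes used in validation are amplitude 2 with noise SD 0.2 (σ = 10 % of
amplitude), folds of 0.5×/2× and shifts of ±4 h, matching the magnitude of
effects such experiments are designed to detect.

Cq tables are generated by inverting the normalization exactly (references
at a flat Cq of 18, targets at Cq = −log_E(value·N)), so the
simulate → normalize round trip is exact at zero noise; Gaussian Cq noise
can be layered on top. Growth tables follow the linear OD→CFU law with
mean-one lognormal noise of a chosen CV, so the calibration stays unbiased
on the original scale.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: plate effects and inter-run drift in
qPCR, non-Gaussian or heteroscedastic expression noise, waveform
distortion (the truth is a pure cosine, so model misspecification is never
exercised), cell-death-driven trends at late timepoints, and lag or
stationary phases in growth curves.

## Numerical choices and validation sizes

Degeneracy (perfect fits) is detected at 10⁻¹² relative to the response
sum of squares. Acrophase of a flat signal is 0 by convention and the wrap
guards the open −2π endpoint against rounding. All simulation streams are
`numpy.random.default_rng` seeded explicitly; identical seeds give
byte-identical CSVs.

Validation uses 10,000 replicates for the type-I error calibration of both
F-tests (accepting [0.04, 0.06] at the 5 % level), 1000 seeds for planted
effect recovery (median fold error < 10 %, median phase error < 0.5 h,
BH-adjusted detection > 90 %), 100 random slices for oracle equivalence
against a direct normal-equations solve at 10⁻⁸, and equivariance checks
(time shift, scaling, label swap) at 10⁻⁹. The smaller in-suite type-I
checks (2000 replicates) use a wider ±1.5 % band consistent with their
binomial standard error.

## Known limitations

* Fixed-period, single-harmonic model: damped or non-sinusoidal rhythms
  bias amplitude and phase estimates.
* Pooling experiments ignores possible batch structure; a mixed-effects
  cosinor is out of scope.
* Delta-method p-values are asymptotic; at n = 24 per condition they are
  mildly anti-conservative for weak rhythms.
* The endpoint module implements direct pairwise t-tests with Sidak
  correction, not a full two-way ANOVA post-hoc reconstruction.
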