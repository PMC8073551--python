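# rhythmfit

Cosinor rhythmometry for qPCR time courses of circadian clock genes, built
for co-culture perturbation experiments: does exposing host cells to a
bacterial strain change the amplitude or phase of their clock-gene
expression?

The package covers the complete analysis chain around that question:

1. **qPCR normalization** — efficiency-corrected relative quantification of
   raw Cq values against the geometric mean of two reference genes
   (*Rplp0*, *ActB* by default).
2. **Cosinor rhythmometry** — per gene and condition, the fixed-period
   single-component cosinor model

   `Y = α·sin(2πt/τ) + β·cos(2πt/τ) + γ`

   is fit by ordinary least squares (τ = 24 h presumed), giving MESOR γ,
   amplitude `A = √(α² + β²)` and acrophase `θ = atan2(−α, β)` wrapped into
   (−2π, 0], with rhythmicity assessed by the zero-amplitude F-test
   (F(2, n−3) against the intercept-only model).
3. **Differential rhythmicity** — control and perturbed slices are stacked
   with a 0/1 condition indicator g:

   `Y = (α₁ + g·α₂)·sin(2πt/τ) + (β₁ + g·β₂)·cos(2πt/τ) + γ`

   The joint null (α₂, β₂) = (0, 0) is tested with a nested F-test;
   amplitude change and phase shift (in hours, positive = the perturbed
   culture peaks earlier) get delta-method p-values; families are adjusted
   by Benjamini–Hochberg (or Sidak).
4. **Endpoint comparisons** — two-sample t-tests of expression at fixed
   late timepoints (24/48/72 h) with Sidak correction and the usual
   `ns/*/**/***/****` labels.
5. **Growth calibration** — the linear OD600 → CFU/mL regression on the
   exponential window (2–5 h) and the culture volume needed for a target
   multiplicity of infection (MOI).

A synthetic-data module generates expression, Cq and growth tables with
exactly the statistical structure these estimators assume, so the entire
chain can be validated end to end without wet-lab data.

## Worked example

Simulate one gene under the study design (samples every 2 h for 24 h, two
independent experiments, noise SD 0.2) with a planted 4.23 h phase advance
in the co-culture, then fit and compare:

```python
import math
from rhythmfit import (GeneTruth, SyntheticDesign, simulate_expression,
                       fit_cosinor, fit_differential)

design = SyntheticDesign(genes=("PER3",), conditions=("K", "BJ17"), seed=42)
truths = {"PER3": GeneTruth(mesor=5.0, amplitude=2.0, acrophase=-math.pi / 2,
                            phase_shift={"BJ17": 4.23}, noise_sd=0.2)}
series = simulate_expression(design, truths)

k = series[series.condition == "K"]
fit = fit_cosinor(k["time_h"], k["value"], period=24.0)
print(f"K: mesor={fit.mesor:.3f} amplitude={fit.amplitude:.3f} "
      f"peak={fit.peak_time:.2f} h  p={fit.p_value:.3g}")

b = series[series.condition == "BJ17"]
diff = fit_differential(k["time_h"], k["value"], b["time_h"], b["value"])
print(f"K vs BJ17: phase_shift={diff.phase_shift_hours:+.2f} h "
      f"amplitude_fold={diff.amplitude_fold:.2f}  p_phase={diff.p_phase:.3g}")
```

prints

```
K: mesor=4.996 amplitude=2.019 peak=5.84 h  p=4.52e-21
K vs BJ17: phase_shift=+4.06 h amplitude_fold=0.97  p_phase=3.55e-243
```

The control gene peaks near 6 h with amplitude ≈ 2 (the planted values) and
is strongly rhythmic; the comparison recovers the planted ~4.2 h advance at
unchanged amplitude and flags the phase shift as significant.

## Command line

Every stage is also a subcommand of the `rhythmfit` CLI:

```bash
rhythmfit simulate --config sim.yaml --out data/ --seed 1
rhythmfit qpcr --cq data/cq.csv --efficiencies data/efficiencies.csv --out series.csv
rhythmfit fit --input series.csv --period 24 --out fits.csv
rhythmfit compare --input series.csv --control K --perturbed BJ17,BJ23 --out diff.csv
rhythmfit endpoints --input series.csv --times 24,48,72 --pairs K:BJ17,K:BJ23 --out ep.csv
rhythmfit growth calibrate --input growth.csv --out cal.json
rhythmfit growth dose --calibration cal.json --od 0.35 --cells 1e6 --moi 0.005
rhythmfit run --config run.yaml       # the whole pipeline from one config
```

Pipeline runs write CSV tables plus a `report.json` whose provenance block
records every convention used (acrophase wrapping, phase-shift sign, mesor
sharing, adjustment families), so reports are interpretable on their own.

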