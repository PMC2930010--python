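# qpcrfit

Quantify target DNA from a **single qPCR amplification curve** by fitting a
two-parameter mass-action kinetic model of PCR (MAK2), alongside the
classic alternatives — Cq standard-curve calibration, exponential
curve-fitting, and 4/5-parameter log-logistic (sigmoid) curve-fitting — and
a dilution-series benchmark for comparing them.

It is aimed at people analysing qPCR data who want absolute-scale estimates
without building a standard curve for every run: single-assay settings,
portable instruments, low-throughput experiments.

## The model

During the anneal/elongation phase of a cycle, single-stranded template is
consumed by two competing reactions: first-order primer binding followed by
polymerase extension (rate constant k₁), and second-order reannealing of
complementary strands (rate constant k₂). With primers and polymerase in
excess and all reactions running to completion within the cycle, the
per-cycle accumulation of double-stranded product integrates to a closed
form,

    Dₙ = Dₙ₋₁ + k · ln(1 + Dₙ₋₁ / k),        k = k₁ / (2 k₂)

where D₀ is the initial template amount and k — the ratio of priming and
reannealing rates — controls how the per-cycle amplification efficiency

    Eₙ = (Dₙ − Dₙ₋₁) / Dₙ₋₁ = (k / Dₙ₋₁) · ln(1 + Dₙ₋₁ / k)

declines from 1 (perfect doubling, D ≪ k) toward 0 as product accumulates.
Observed fluorescence is modelled as Fₙ = Fb + Dₙ with a constant
background Fb. The model holds only before primer depletion and enzyme
saturation, so curves are truncated at the cycle of maximum slope increase
(maximum second difference of the raw fluorescence) before fitting; the
three parameters (D₀, k, Fb) are then estimated by Nelder-Mead minimisation
of the sum of squared residuals, and the fitted D₀ is the quantification —
no standard curve required. A numerical integrator for the underlying
within-cycle kinetics (`qpcrfit.kinetics`) cross-checks the closed form.

## Worked example

```python
from qpcrfit import GeneratorConfig, generate_dilution_series, fit_mak2, calibrate_series

config = GeneratorConfig(seed=1)                      # six ten-fold levels, duplicates
synth = generate_dilution_series(config)

curve = synth.series.curves[6]                        # one well at D0 = 1e-5
result = fit_mak2(curve)
print(f"{curve.well_id}: D0 = {result.estimate_d0:.3e}  k = {result.params['k']:.3f}  "
      f"Fb = {result.params['fb']:.3f}  cycles 1..{result.cycles_used[1]}  SSR = {result.ssr:.2e}")

cal = calibrate_series(synth.series, "mak2")
print(f"calibration: slope = {cal.slope:.4f}  R^2 = {cal.r_squared:.4f}  wells = {cal.n_used}")
```

prints

```
L3R0: D0 = 1.016e-05  k = 0.529  Fb = 1.001  cycles 1..16  SSR = 1.12e-03
calibration: slope = 0.9997  R^2 = 0.9994  wells = 12
```

The single-well fit recovers the generating template amount (10⁻⁵ in
arbitrary fluorescence units) to within 2% despite 1%-of-plateau detector
noise, using only cycles 1–16 of the curve. Across the whole series the
log-log regression of estimated against known amounts has slope ≈ 1 and
R² ≈ 0.999: estimates are proportional to input over five decades.

Estimators follow the scikit-learn protocol
(`MAK2Regressor().fit(X, y)` with cycle numbers in `X`, fluorescence in
`y`, fitted attributes `d0_`, `k_`, `fb_`), so they compose with sklearn
tooling; `fit_mak2` and friends are thin wrappers.

A CLI covers the same pipeline:

```
qpcrfit simulate --seed 1 --out curves.csv --truth-out truth.csv
qpcrfit compare curves.csv --methods mak2,cq,exponential,loglogistic4,loglogistic5 \
        --out-prefix report --plot
```

`report.csv` holds one row per well per method, `report.json` the
per-method slope/intercept/R², `report.png` the log-log estimated-vs-known
panels with the 45° agreement line.

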