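# Methods

## The kinetic model

One PCR cycle's anneal/elongation phase is modelled as two competing
consumers of single-stranded template S: first-order priming-and-synthesis
(rate k₁·S; each primed strand is extended into one new duplex by
non-limiting polymerase) and second-order reannealing of complementary
strands (rate k₂·S²; two strands re-form one duplex without synthesis).
The assumptions are those of an idealised early-cycle reaction: error-free
polymerase; both strands and both primers treated identically; primers and
polymerase in excess ("non-limiting"), which implies all reactions run to
completion within the cycle; elongation as a single step; and complete
melting at the denaturation step, so each cycle starts from S₀ = 2·Dₙ₋₁
single strands.

Integrating dS/dt = −k₁S − k₂S² to exhaustion gives the primed amount
P = (k₁/k₂)·ln(1 + k₂S₀/k₁); with Dₙ = Dₙ₋₁ + P/2 this is exactly the
closed-form recursion

    Dₙ = Dₙ₋₁ + k·ln(1 + Dₙ₋₁/k),   k = k₁/(2k₂).

`qpcrfit.kinetics` integrates the ODE numerically (nondimensionalised to
the single parameter ρ = k₂S₀/k₁; LSODA, relative tolerance 1e-10,
completion declared when the single-stranded fraction falls below 1e-12)
and serves as an independent oracle: the proportionality constant between
k₁/k₂ and the recursion's k is calibrated numerically on one parameter set
(`calibrate_convention`, a Brent solve matching one integrated cycle to the
closed-form gain) and verified parameter-independent across a grid; it is
1/2, the footprint of the 2:1 single-strand/duplex bookkeeping at the melt
step.

Two consequences shape everything downstream. The per-cycle efficiency
(k/D)·ln(1+D/k) declines monotonically from 1 as product accumulates —
constant-efficiency quantification is an approximation, not a property of
the mechanism. And the trajectory has no inflection point (second
differences are strictly positive), so once a measured curve inflects the
model no longer applies.

## Fitting procedure

Curves are truncated at the cycle with the maximum slope increase — the
argmax of the plain second difference of raw fluorescence (no smoothing,
no statistical outlier classification; ties break to the earliest cycle).
Empirically the inflection follows shortly after this cycle, so the
retained prefix stays inside the model's validity region. The background
is initialised from the mean of the early cycles (by default up to two
cycles before the cutoff, at least three cycles).

The SSR between Fb + Dₙ and the observed fluorescence over the retained
cycles is minimised by Nelder-Mead (iteration cap 5000, SSR-relative
convergence 1e-10) in (log₁₀D₀, log₁₀k, Fb) — the log parameterisation
enforces positivity without constraints. Because no initialisation is
canonical, a small deterministic multi-start grid is used: the
scale-aware heuristic start (Fb from the baseline, D₀ at 1e-4 of the
maximum background-adjusted signal, k at the maximum first difference over
ln 2) plus starts with log₁₀D₀ offset by −2, −4, −6, −8 from the maximum
adjusted signal; best SSR wins. All fits are deterministic.

A retained window whose maximum background-adjusted signal is below five
baseline standard deviations raises a no-amplification error: a flat noisy
well (negative control) must be excluded, not quantified. This operational
detection limit (~5σ) means genuinely amplifying but extremely weak wells
are also refused.

### Comparator methods

* **Cq**: threshold at a fraction (default 10%) of the maximum
  background-adjusted signal — dataset-wide when calibrating a series, or
  an absolute threshold supplied per dataset — with the crossing cycle
  linearly interpolated. On ideal doubling data the Cq-vs-log₁₀(copies)
  slope is −log₂10 ≈ −3.32 cycles per decade.
* **Exponential**: Fₙ = Fb + F₀(1+E)ⁿ fitted by bounded least squares over
  an expanding window from cycle 1; the first window accepted must
  converge, have E > 0.01, and beat a straight-line fit by more than 5% in
  SSR (the "minimum data supporting a genuinely nonlinear fit",
  operationalised); the window never extends past the truncation cycle.
* **Log-logistic (4/5 parameter)**:
  F(n) = Fb + (Fmax−Fb)/(1+exp(b(ln n − ln e)))^f fitted to the full curve
  (the plateau is what identifies Fmax); f ≡ 1 in the 4-parameter case.
  Fits whose column-scaled Jacobian condition number exceeds 1e8 or whose
  Fmax has a relative standard error above 0.25 are flagged
  ill-determined — the signature of a curve without a plateau. The initial
  amount is estimated in a second stage: the fitted sigmoid is evaluated
  over the curve's cycles and the exponential model is fitted to those
  predictions over the exponential-phase window only — from the takeoff
  (0.5% of the signal at the max-slope-increase cycle) to that cycle.
  Below takeoff a log-logistic tail grows as a power of the cycle number,
  not exponentially, and including it corrupts F₀ by orders of magnitude.

### Calibration benchmark

For a dilution series, each well's metric (log₁₀ of the D₀/F₀ estimate, or
the Cq) is regressed on log₁₀ of the known template amount by unweighted
OLS; estimated amounts are back-predicted by inverting the trend line, so
perfectly proportional estimates reproduce the knowns exactly. Wells whose
fit fails are excluded with a logged machine-readable reason, never
imputed. The k-diagnostic regresses fitted k on log₁₀(known): k should be
constant for a given amplicon and primer set, and a nonzero trend flags
effects outside the model.

## Synthetic data generator

Curves are generated as Fₙ = Fb + saturate(Dₙ) + εₙ with Dₙ from the
recursion, additive homoscedastic Gaussian noise εₙ, and a smooth
saturating hand-off emulating primer depletion/polymerase saturation —
phenomena deliberately outside the kinetic model. The hand-off is the
identity up to 0.3·Fmax and θ + span·tanh(u + u³/3) above it
(u = (D−θ)/span): slope-continuous at the hand-off, deviating from the
identity only at fifth order, then approaching the ceiling decisively, as
real reactions do once primers run short.

Defaults, chosen once as the package's study conditions: six ten-fold
levels of D₀ from 1e-8 to 1e-3 (arbitrary fluorescence units; the
copies-to-signal factor defaults to 1 because quantification is relative),
k = 0.5, Fb = 1.0, plateau 1.0 above background, 40 cycles, noise SD 0.01
(1% of plateau), two replicates. k = 0.5 in plateau units keeps per-cycle
efficiency above ~0.9 until saturation and gives the 10–90% rise in ~3–4
cycles seen in high-efficiency dye-based assays; it also keeps the curve's
maximum slope increase (~0.1 of plateau) well above what 1%-of-plateau
noise produces in second differences, which the raw-difference truncation
rule needs to be reliable. An optional linear-in-log₁₀(D₀) drift of k
across levels supports diagnostic studies. Per-well noise streams are
keyed on (seed, level, replicate), so output is reproducible and
independent of generation order, and the generator always returns the
per-curve truth (D₀, k, Fb, known copies) for recovery testing.

What the generator does *not* emulate: amplification inhibitors,
heteroscedastic or multiplicative noise, melt/probe chemistry, pipetting
error in the dilution structure, and between-run drift. Passing tests
therefore show that the estimators recover what this data-generating
process encodes — exponential-phase kinetics with additive detector noise
and a plateau — not that they are robust to every artefact of real runs.

## Numerical choices

* ln(1 + D/k) is evaluated with `log1p`; above D/k = 1e15 the asymptotic
  k·ln(D/k) form avoids overflow (dilution series span many decades).
* The log-logistic sigmoid is evaluated via a softplus form to avoid
  overflow at extreme shape parameters.
* Nelder-Mead: per-start cap 5000 iterations, simplex tolerances
  xatol 1e-9 and fatol 1e-10 relative to the starting SSR. Least-squares
  fits (exponential, log-logistic) run bounded trust-region reflective
  with 1e-14/1e-15 tolerances.
* Degenerate inputs: no-template simulation is allowed (flat trajectory);
  efficiency is undefined at D₀ = 0 and raises; negative-control wells are
  flagged/excluded rather than fatal throughout the pipeline.
* Cq crossings exactly at a cycle interpolate to that integer cycle; a
  crossing at cycle 1 is reported as Cq 1 with a warning flag.

## Known limitations

* Fitted k is attenuated at steep curves: the retained window ends at the
  maximum-slope-increase cycle, whose fluorescence is already slightly
  saturation-bent, and the bias grows superlinearly with k/plateau (≈9% at
  the default k = 0.5, ~30% by k = 1). D₀ recovery is far less affected
  (within 0.01 decades noiseless, 0.1 decades at 1% noise). The
  k-vs-log₁₀(D₀) diagnostic consequently under-reports drifts that push k
  toward the steep regime.
* Cutoff-shift robustness (±1–2 cycles barely moving log₁₀D₀) holds when
  the cutoff sits inside the model's validity region (gentle knees, e.g.
  k ≈ 0.05·plateau); at the steep default a +2-cycle shift reaches
  saturation-bent data and can move log₁₀D₀ by ~0.3.
* The truncation rule takes a raw argmax; at noise levels much above 1% of
  plateau, or for curves whose knee is shallow relative to noise, a noise
  spike can win and the well is then rejected by the signal check rather
  than recovered.
* Estimates are relative (arbitrary fluorescence units); converting to
  absolute copies requires a calibration series, as does any cross-dataset
  comparison.
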