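# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package.  Units follow field
convention: energies in cal/mol, entropies in cal/(mol·K), temperatures in
°C for melts and K for rate laws, ellipticity in mdeg, HT voltage in volts.

## Rate extraction

Absorbance traces of NADPH depletion at 340 nm are zero-order under
saturating substrate and cofactor, so the initial velocity is the OLS slope
of A(t) over the first 15 s (at least 5 samples required), converted to
molar units by Beer–Lambert with ε = 13.2 mM⁻¹cm⁻¹ and the cuvette path
length; kcat = v₀/[E].  Negative velocities (rising absorbance) are
returned unclamped so that pathological traces surface downstream rather
than silently becoming zeros.

## Eyring analysis

`fit_eyring` uses the linearized form

    ln(kcat/T) = [ln(kB/h) + ΔS‡/R] − (ΔH‡/R)·(1/T)

solved by closed-form OLS.  The linearized fit was chosen as the primary
route because it is deterministic, has no convergence failures inside the
bootstrap loop, and on noiseless data agrees with a direct nonlinear SSE
minimization to the resolution of a 0.2 cal/mol grid search (asserted in
tests).  Temperatures above `t_max` (default 35 °C) are excluded before
fitting and before resampling: the fusion's Tm is below 40 °C, so rates
measured there mix catalysis with denaturation.  Kelvin conversion uses
273.15 throughout (the two-state melt literature sometimes prints 273; the
difference is below reporting precision).

`bootstrap_eyring` resamples the pooled filtered (T, kcat) pairs with
replacement, n_boot = 5000 by default, refitting each draw (vectorized
closed form).  Draws with fewer than two distinct temperatures cannot
identify a slope and are redrawn (counted in `n_redrawn`; at 21 points over
7 temperatures this is vanishingly rare).  `stratified=True` instead
resamples replicates within each temperature.  Standard errors are
bootstrap standard deviations; CIs are 2.5/97.5 percentiles.  Point
estimates always come from the full data, never the bootstrap mean.
Calibration: across 1000 simulated panels at 5% replicate CV, the 95%
percentile CI for ΔH‡ covers the generating value ~92% of the time — the
mild undercoverage expected of percentile intervals at n = 21.

Lit-minus-dark energetics pair iteration i of the lit bootstrap stream
with iteration i of the independent dark stream; since the two experiments
are independent, this is the standard independent-condition bootstrap for a
difference.  The printed-style entropy term is exposed both as ΔΔS‡
(cal/mol/K) and as T·ΔΔS‡ at the reference temperature (cal/mol, default
303.15 K), because cross-study reports commonly print the product.
The identities ΔΔG‡ = ΔΔH‡ − T·ΔΔS‡ and fold = exp(−ΔΔG‡/RT) hold exactly
for every output object, including per-iteration bootstrap vectors.

## Chromophore relaxation

Dark recovery of the flavin adduct at 447 nm is fit with one-phase
association, A(t) = plateau + (A₀ − plateau)e^(−kt), by nonlinear least
squares with k bounded positive, initialized from the trace endpoints and
the half-recovery time.  A constant trace leaves k unidentifiable and
raises an error instead of returning a number.

## CD melt cleaning

**Pulse removal.**  Measurements that coincide with an excitation-LED pulse
show a transient dip in the photomultiplier HT voltage.  The detector flags
samples where the first difference of HT drops below k·MAD (k = 5) of the
successive-difference distribution *and* recovers on the next sample.  The
recovery requirement is what distinguishes a single-sample pulse dip from
the sustained HT collapse of aggregation, which must never be removed as an
artifact; dips in the first or last sample are flagged from the one
observable flank.  The exact threshold the original instrument software
used is not documented; k = 5 is a default, not a claim.

**Dual-wavelength averaging.**  Melts are recorded at 222 and 222.1 nm so
that a pulse-corrupted read has a surviving twin.  After pulse removal the
two channels are averaged by nearest-temperature pairing within half a ramp
step; unpaired rows survive as singles (that is the point of the duplicate
reads), and their count is logged.

**Replicate scans.**  Thermal melts are commonly acquired as triplicate
scans and fit jointly; `merge_melt_scans` pools cleaned scans onto one
sorted grid.  The calibration experiments use three scans per melt, which
brings the Tm sampling error at 0.2 mdeg CD noise to about 0.1 °C.

## Fit window from the HT channel

Dark-state melts of the photoswitch aggregate above ~50 °C: ellipticity at
222 nm surges while the HT voltage collapses, and visible precipitate forms.
The two-state fit window therefore starts at the lowest measured
temperature and ends halfway between the temperature of maximum CD and the
temperature of maximum HT.  Two estimation details matter:

- *Aggregation detection.*  If the HT channel does not lose at least 25% of
  its dynamic range after its peak, there is no aggregation signature and
  the full ramp is used (lit-state behavior).
- *Temperature of maximum HT.*  HT rises with the unfolded fraction and
  plateaus once unfolding completes, so under noise the literal argmax
  wanders over the plateau and can even land inside the decay region.  The
  peak temperature is instead taken as the first attainment of the smoothed
  HT maximum within 0.5% of the channel's dynamic range, which pins the
  endpoint just below the aggregation onset.

If the midpoint would leave fewer than 10 °C of data, the full range is
used and the fallback is logged.  The window interpretation ("halfway"
read on the temperature axis between the two channel maxima) is the main
interpretive decision in the package; a value-axis reading is not
implementable as a fit bound.

## Two-state fit

Nonlinear least squares over (ΔH, Tm, F, Cf, U, CU) with ΔH constrained
negative.  Initialization: Tm from the extremum of a 5-point
moving-average dCD/dT on the per-temperature means; baselines from linear
fits to the outer 20% temperature segments; ΔH from −50,000 cal/mol.  The
exponent is clipped at ±700 to avoid overflow.  A fit is *flagged* (never a
silent number) when the optimizer fails, Tm falls outside the window, or
the fitted transition amplitude at Tm is indistinguishable from the
baselines (below 5·rms or 0.1% of the data range) — the latter catches
pure-baseline traces.  Tm is invariant to affine rescaling of the CD
channel, so fitting in mdeg or mean-residue ellipticity is equivalent.

ΔG of unfolding is deliberately not computed: thermal unfolding of the
fusion is not reversible, so the fitted ΔH is a fit-internal shape
parameter and only Tm is reported as a thermodynamic quantity.  (Figure
captions in the source literature for such fits occasionally say
"three-state"; the fitted model here is the two-state equation above.)

## Synthetic-data generator

Every generator is a pure function of (parameters, seed) — identical inputs
reproduce identical output bit for bit — and noiseless output equals the
corresponding forward model to machine precision, which is what makes
round-trip validation of the fitters meaningful.

- *Absorbance traces*: A(t) = A₀ − ε·l·[E]·kcat·t + N(0, σ), floored when
  the limiting species is exhausted.  A hard floor (not Michaelis–Menten
  rollover) because the emulated assays are saturating.
- *Rate panels*: kcat drawn as Eyring(T)·exp(N(0, ln(1+cv))).  The noise is
  multiplicative lognormal — rates are positive and kinetic replicate
  scatter scales with the rate; cv defaults to 0.05, a typical replicate
  spread for manual-mixing spectrophotometric assays.
- *Melts*: two-state CD plus Gaussian noise (default 0.2 mdeg), duplicate
  222/222.1 nm rows, an HT channel rising 60 V over a 300 V base with the
  unfolded fraction, square HT dips (30 V) plus a −12 mdeg CD corruption at
  rows whose 1-s integration window overlaps a 250 ms pulse on a 10 s
  period mapped onto the 61.3 s-per-step ramp cadence, and optionally the
  aggregation signature.  Baselines default to F = −20.5, Cf = 0.05,
  U = −6.0, CU = 0.02 (mdeg, mdeg/°C) — a ~13 mdeg transition amplitude
  typical of a 1 mg/ml sample in a 1 mm cuvette at 222 nm.
- *Aggregation*: above the onset (default 50 °C) the CD excess rises
  linearly at 6 mdeg/°C but is damped exponentially with a 3 °C scale as
  precipitating material leaves the beam, producing a sharp transient spike
  peaking a few degrees above onset; HT decays exponentially at 0.03/°C.
  The spike-then-fall shape (rather than an unbounded monotone surge) is
  deliberate: scattering material that leaves solution stops contributing
  ellipticity, and it is the only shape under which the published
  HT-midpoint endpoint rule actually isolates the two-state region.
- *Relaxation traces*: the one-phase model plus noise.

What the generator does **not** emulate: photocycle photophysics, slow
instrument drift, temperature-lag between the block and the cuvette,
refolding hysteresis, aggregation kinetics beyond the qualitative
signature, and Michaelis–Menten behavior away from saturation.  Passing
recovery tests therefore demonstrates the pipeline's correctness under the
stated statistical model, not robustness to every real-instrument
pathology.

## Calibration experiments (study conditions)

`calibration.py` fixes the generating values at the published numbers:
dark ΔH‡ anchored at 14,000 cal/mol with ΔS‡ chosen to give the printed
0.58 /s at 25 °C, ΔΔH‡ = −1665 cal/mol, T·ΔΔS‡ = −1536 cal/mol at 30 °C
(or an entropy shift giving the printed 34% activation at 25 °C), dark/lit
Tm of 33.9/31.3 °C with ΔH_fold = −60,000 cal/mol.  Problem sizes are the
study's: 7 temperatures × 3 replicates, 5000 bootstrap iterations, 0.5 °C
melt steps over 5–80 °C with triplicate scans.  One hundred seeded runs of
the kinetic recovery take ~2 s on one CPU.

## Cross-variant analyses

Aggregation of per-variant results never refits anything.  Classification
of allosteric effect uses the fold-change CI: a record with exactly zero
effect is always neutral; otherwise the CI is compared against 1 (no
reference) or against the reference construct's CI (overlap = neutral,
strictly above = enhancing, strictly below = disrupting) — the underlying
study states no explicit rule, so this one is documented here.  The
stability–activity line of best fit takes its exclusion set as an explicit
argument (default exclusions in the examples: the three light-stabilized
variants), and the reverse regression is reported alongside because the
fitting direction of such tradeoff plots is a convention.  The
`SYNTHETIC_PANEL` truth table is a synthetic illustration: only the
reference construct's row uses published values.

## Known limitations

- Percentile bootstrap CIs at n = 21 undercover slightly (~92% for a
  nominal 95%); se-based intervals are available from the same vectors.
- The melt fit treats scan-to-scan variation as iid noise; real replicate
  scans can carry correlated drift.
- The pulse detector assumes dips are isolated (non-adjacent rows); an
  acquisition cadence phase-locked to the pulse period would violate this
  and should be fixed at the instrument, not in software.
- `fit_window` assumes at most one aggregation transition above the
  unfolding transition.
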