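# Methods

## Measurement model

A whole-body tetrapolar impedance sweep is modelled by the Cole dispersion

    Z(f) = [R∞ + (R₀ − R∞) / (1 + (j f / f_c)^α)] · exp(−j 2π f T_d)

with zero- and infinite-frequency resistances R₀ > R∞ > 0 (Ω),
characteristic frequency f_c (Hz), broadening exponent α ∈ (0, 1], and a
time delay T_d (ns) multiplying the spectrum as a pure phase factor.
T_d models high-frequency measurement artefacts (cable/electrode delay):
it leaves |Z| untouched and rotates the phase by −2π f T_d. Reactance is
stored signed (capacitive X_c < 0); any magnitude display is presentation
only.

Under the parallel two-branch interpretation of tissue, the extracellular
branch resistance is Re = R₀ and the intracellular branch resistance is
Ri = R₀·R∞/(R₀ − R∞); R₀ ≤ R∞ is non-physical and is flagged, never
silently propagated.

## Spectrum fitting

`fit_cole` minimises the unweighted sum of squared complex residuals
(real and imaginary parts stacked) over (R₀, R∞, f_c, α, T_d) with a
trust-region-reflective least-squares solver.

* Initialisation: R₀ = 1.05·R(f_min), R∞ = 0.95·R(f_max), f_c at the |X_c|
  maximum, α = 0.7, T_d = 0.
* Bounds: α ∈ (0.3, 1], f_c ∈ [1 kHz, 5 MHz], T_d ∈ [−5, 5] ns.
* Convergence: relative objective/step/gradient tolerance 1e-10, at most
  500 iterations (2500 function evaluations).
* A spectrum with fewer than 10 frequencies is rejected outright; one whose
  span is under a decade is fitted but reported `converged=False`, because
  R₀ and R∞ are then not identifiable — downstream stages treat such fits
  as absent rather than trusting extrapolated values.

Measurements are kept iff |T_d| ≤ 0.5 ns (closed interval, threshold
configurable). The interval is closed so that a fit landing exactly on the
threshold is retained; the units are nanoseconds throughout.

Single-frequency readout (`resistance_at`) returns stored values on-grid
and interpolates R and X_c separately, linearly in log-frequency,
off-grid; it refuses to extrapolate outside the measured band.

## Predictors

Four 50 kHz regressions (H in cm, W in kg, age in years, sex 1 = male,
0 = female, output litres):

| method      | form |
|-------------|------|
| Deurenberg  | 6.69 + 0.34573·H²/Z₁₀₀ + 0.17065·W − 0.11·age + 2.66·sex |
| Heitmann    | −17.58 + 0.240·H²/R₅₀ − 0.172·W + 0.40·sex·W + 0.165·H |
| Kushner     | men 8.399 + 0.396·H²/R₅₀ + 0.143·W; women 8.315 + 0.382·H²/R₅₀ + 0.105·W |
| Sun         | men 1.203 + 0.499·H²/R₅₀ + 0.176·W; women 3.747 + 0.450·H²/R₅₀ + 0.113·W |

Deurenberg's impedance input is |Z| at 100 kHz taken from the measured
(or interpolated) spectrum, not from the Cole fit. The Heitmann "sex
weight" term is read as the product sex·weight.

Mixture theory (classical): ECW = (1/1000)(K_b²ρ_e²/D_b)^{1/3}
(√W·H²/Re)^{2/3} with K_b = 4.3, D_b = 1.05×10⁻³ kg/cm³, ρ_e = 40.5 Ω·cm
(men) / 39.0 (women), ρ_i = 273.9 / 264.9. This grouping of the constants
evaluates to the prefactors 0.3068 (men) and 0.2992 (women) familiar from
the BIS literature, which is why it was chosen over other readings of the
formula. The ICW/ECW ratio x solves

    (1 + x)^{5/2} = ((Re + Ri)/Ri) · (1 + (ρ_i/ρ_e) x),

whose right-hand side has k = (Re+Ri)/Ri ≥ 1; g(x) = LHS − RHS has
g(0) = 1 − k ≤ 0 and grows without bound, so a single positive root is
bracketed on (0, 20] and found by Brent's method (xtol 1e-14). Two
consequences of this relation worth knowing:

* with ρ_i/ρ_e ≈ 6.8 a positive Ri exists only for x ≳ 1.81, i.e. the
  model cannot represent small ICW/ECW ratios at all;
* as Ri → ∞ (k → 1⁺) the root tends to that boundary ≈ 1.81, not to 0;
  x = 0 is returned only when k == 1 exactly.

The BMI-compensated variant applies K_ef = 0.188/BMI + 0.2883 to
(H²√W/Re)^{2/3} and K_if = 5.8758/BMI + 0.4194 to the same quotient in Ri.
Both BIS methods report TBW = ECW + ICW. Volumes outside 10–70 L, or
ratios outside 0.3–4, are QC-flagged in the output but never filtered;
flags surface model breakdown without altering the statistics.

## Agreement battery

Differences are reference − predicted (positive bias = under-prediction);
percentage differences divide by the reference dilution volume. Limits of
agreement are bias ± 2·SD exactly (literal 2, not 1.96). Lin's concordance
uses n-divisor moments: r_c = 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²). SEE is
√(RSS/(n−2)) from OLS of reference on predicted. MAPE is the mean of
100·|predicted − reference|/reference, with a percentile bootstrap CI of
the mean (2000 resamples, seeded). The trend statistic correlates the
differences with the reference volume (primary) and with the pair mean
(classical variant, also emitted). All statistics require n ≥ 3 and
non-zero variance, and are invariant to subject order.

The frequency sweep correlates H²/R(f) with reference TBW and ECW at every
grid frequency, plus extrapolated points at 0 and ∞ computed from the
fitted R₀ and R∞ (emitted as sentinel rows 0/inf in the sweep table).

## Synthetic cohort generator

Defaults emulate the study population: age 61 ± 14 y, height 172 ± 10 cm,
weight 84.9 ± 16.9 kg applied to both sexes (only pooled moments are
reported for the source cohort), 56:38 male:female, n = 94. Per subject:

* TBW = weight × fraction, fraction ~ N(0.55 men / 0.50 women, 0.05),
  truncated to (0.3, 0.75);
* ICW/ECW ratio x ~ N(2.6, 0.3) truncated to (1.95, 3.6). The centre is
  anchored to the observable dispersion depth: x ≈ 2.6 maps to
  R₀/R∞ ≈ 1.33, the ratio whole-body spectra typically show. The lower
  truncation keeps draws inside the mixture-representable region
  (x > 1.81); physiological text-book ratios nearer 1.3 are simply not
  expressible by these equations;
* (Re, Ri) by exact algebraic inversion of the mixture equations, so the
  classical BIS predictor recovers the simulated truth exactly in the
  noiseless limit — the closure property the test-suite leans on;
* Cole parameters: R₀ = Re, R∞ from the parallel identity,
  f_c ~ N(40, 8) kHz, α ~ N(0.70, 0.03) — typical whole-body values;
* T_d ~ N(0.29, 0.14) ns truncated to |T_d| ≤ 0.5 (the artefact-free
  band); a configurable `artifact_fraction` of subjects instead draw
  |T_d| ~ U(0.6, 2.0) ns with random sign, so the kept fraction under the
  filter is exactly binomial;
* spectra on 50 log-spaced frequencies 5 kHz–1 MHz with the nearest points
  snapped to exactly 50 and 100 kHz; i.i.d. Gaussian noise (default
  0.5 Ω) on each R and X_c value;
* dilution references = truth × (1 + N(0, CV)) with CV 1.5%, a plausible
  precision for dilution assays.

All randomness flows from one root seed through per-subject child streams,
so cohorts are bit-reproducible and subject i's draw does not depend on
cohort size. Truncated normals are rejection-sampled with 100 retries;
exhaustion signals misconfigured SDs rather than looping forever.

What the generator does **not** emulate: covariance between anthropometric
variables (age–BMI correlation etc.), biological discordance between the
measured impedance and the idealised mixture law, electrode placement and
segmental geometry, and population-specific calibration of the regression
equations. Consequently the synthetic biases of the single-frequency and
BMI-compensated methods measure their mismatch against this particular
generative model, not their clinical accuracy — only the structural
properties (closure, recovery, filter bookkeeping, statistic definitions,
frequency ordering) transfer to real data.

## Known limitations

* **ECW correlation peak location.** Because the generator is exactly
  mixture-consistent, ln(H²/Re) loads the ratio term ln(1+x) with weight
  1.5 while ln ECW loads it with 1.0; a mid-frequency quotient partially
  cancels the excess and the ECW correlation therefore peaks near 0.6·f_c
  (≈ 20–25 kHz) rather than at the bottom of the band, and its exact
  argmax jitters among the flat low-frequency points under measurement
  noise. Real cohorts, where biological scatter dominates, show the peak
  at the lowest measured frequencies. The TBW peak at the top of the band
  is robust in both.
* The mixture equations' representable range (x ≳ 1.81) forces synthetic
  ECW fractions of body weight (~0.15) below typical physiological values
  (~0.20–0.25); this is a property of the published constants, not of the
  implementation.
* The Heitmann interaction reading (0.40·sex·weight) follows the printed
  form; its original coding convention should be checked against the
  source publication before clinical use.

## Problem sizes

The test-suite uses cohorts of 16–500 subjects, 200 replicate fits for
noise-recovery checks, 1000 random draws for the solver/oracle and
concordance-inequality properties, and 200 simulated samples at 200
bootstrap replicates for CI coverage; the full suite runs in well under a
minute. The reproduction script simulates 94 subjects with 2000 bootstrap
resamples and finishes in a few seconds.
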