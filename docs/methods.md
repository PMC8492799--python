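# Methods

This note documents the models implemented in `bbbleak`, the assumptions
behind them, the defaults of the synthetic-data generators, and the
numerical and design choices made where the problem left room.

## Imaging chain

### Acquisition model

The simulated acquisition mirrors a dual-time-resolution DCE protocol at
3 T: a fast dynamic sequence (dynamic scan time 3.2 s, 29 volumes) samples
the bolus first pass, followed by a slow sequence (30.5 s per volume,
45 volumes) that follows the subtle leakage phase for roughly 23 minutes.
Both sequences share the SPGR readout (TR 5.6 ms, TE 2.5 ms). Volume
timestamps use the midpoint convention. Pre-contrast baseline volumes
(defaults: 2 fast, 1 slow) define the per-voxel baseline S₀; the slow
sequence's baseline is placed before the fast block, which is how an
integrated dual sequence acquires it in practice. The bolus injection
delay relative to the start of the fast sequence is a parameter
(`PhantomConfig.injection_time`, default: right after the fast baselines),
with a further 4 s arm-to-head transit before the bolus reaches the brain.

Parameters not fixed by the protocol and their defaults:

- flip angle 10° — typical 3 T DCE value; every routine works for any
  angle in (0°, 90°].
- relaxivity r₁ = 5.0 L·mmol⁻¹·s⁻¹ — gadobutrol at 3 T.
- hematocrit 0.45 — standard large-vessel value for the plasma conversion.
- `s0_scale` = 2000, giving a white-matter SPGR baseline of ~100 signal
  units, so the default noise SD of 1.0 is ~1% of baseline (SNR ≈ 100).

### Vascular input function

Patient studies measure the input function in the superior sagittal sinus;
the phantom replaces it with a parametric, causal, analytically integrable
curve: a gamma-variate first pass (plasma peak 8 mmol/L, time-to-peak 10 s,
shape α = 3) plus a washout term a·(e^(−t/600 s) − e^(−t/15 s)) that
sustains a ~1 mmol/L plasma plateau decaying with a 10-minute time
constant — the magnitudes expected for a standard 0.1 mmol/kg bolus at
3 ml/s. Closed-form running integrals (incomplete-gamma and exponential
antiderivatives) make the Patlak forward model exact, so the fitting chain
can be validated against truth rather than against another numerical
integral. Boxcar and biexponential shapes are provided for oracle tests.

Sinus voxels carry whole-blood concentration C_b = (1 − Hct)·C_p; the
extraction stage averages them spatially, applies the hematocrit
correction, and integrates by the trapezoid rule on the merged time grid.

### Noise model

Zero-mean Gaussian noise on the signal (default), reflecting the high-SNR
magnitude regime of these acquisitions; a Rician option exists for
sensitivity analyses but is not the default. Signal noise propagates
through the SPGR inversion into approximately symmetric concentration
noise and, through the Patlak fit, into a per-voxel Ki uncertainty of a
few 10⁻⁵–10⁻⁴ min⁻¹ at the default SNR — deliberately the same order as
the ground-truth leakage rates, because that near-noise-floor regime is
what the histogram correction exists for.

### Signal → concentration

Per voxel: S₀ = mean of pre-contrast volumes; the SPGR equation is
inverted using S₀ and the voxel's T₁₀ (the equilibrium-magnetization term
cancels), giving R₁(t) and C(t) = (R₁(t) − 1/T₁₀)/r₁. Samples outside the
invertible range (noise pushing the signal past the SPGR saturation
ceiling) are clamped at a physical concentration ceiling of 50 mmol/L and
counted in the QC report; without the ceiling a single saturated sinus
sample can dominate the spatial average of the input function. Voxels with
S₀ ≤ 0 are flagged invalid and excluded. A first-order fallback
(C ≈ RE/(k·r₁), with k the SPGR enhancement sensitivity at baseline) is
available for degenerate protocols.

### Patlak fit

Voxel-wise OLS of y = C_t/C_p on x = ∫C_p/C_p over the fit window. The
default window starts at the first slow-sequence volume — after the first
pass, where the well-mixed-plasma linearity assumption of the Patlak model
holds — and runs to the end. Time points with C_p below 10⁻³ mmol/L are
excluded (division stability); voxels with fewer than 3 usable points are
invalid. Slopes are converted to min⁻¹ exactly once (a single ×60 at the
map boundary; all internal time is seconds). Negative slopes are retained:
the histogram correction requires the full sign-symmetric noise
distribution. The intercept (plasma fraction v_p) is computed and stored
but plays no role downstream.

The closed-form shared-design OLS (one x vector for all voxels) makes the
fit O(voxels × timepoints); the default 32×32×10 phantom quantifies in
well under a second.

## Histogram noise correction

Per region, Ki values are binned with edges anchored at 0 (default width
0.2 ×10⁻⁴ min⁻¹, resolving rates of 1–5 ×10⁻⁴ min⁻¹ with ≥10 bins);
positive bins are right-closed, negative bins their mirror images. The
negative half is mirrored and subtracted bin-by-bin with clamping at zero
— detectable leakage cannot be negative mass. From the corrected positive
histogram: v_L = 100 × remaining mass / region voxels (%), and mean Ki =
count-weighted mean of bin centers (10⁻⁴ min⁻¹). If nothing remains, both
are zero and the result is flagged.

Choices within this scheme:

- **Bin-level subtraction** is the default; a voxel-level variant (remove,
  per positive bin, as many actual voxel values as the mirrored bin holds)
  exists for sensitivity analysis. The two agree on detected mass exactly
  and on mean Ki to within a bin width.
- **Voxels with Ki exactly 0** belong to neither histogram side: a zero
  voxel carries no sign information and cannot contribute detectable
  leakage. They stay in the denominator (`n_total`) and are tracked in a
  separate `n_zero` field; with any noise they form a measure-zero set.
- **mean Ki from bin centers**, not from matched voxels: the correction is
  defined on the histogram, and voxel-level subtraction is not uniquely
  defined. The discretization error is bounded by half a bin width.

Interpretation caveat: with noise comparable to the true rates, the
correction removes symmetric mass around zero, so the surviving mass
over-represents the upper tail — mean Ki is an estimate of the *detectable*
leakage rate, biased upward relative to the ground-truth mean, and v_L is
the detectable fraction, not the true leaky fraction. The tests quantify
both behaviors (exact recovery at zero noise; bounded deviation at finite
noise).

## Cognitive compounds

Raw decline = baseline − follow-up per test; tests whose raw scale is
"higher is worse" (Stroop Color-Word and Trail-Making times) are inverted
so positive decline always means worsening. Declines are z-standardized
over the analysis cohort with the sample SD (n−1 denominator), averaged
within domain (memory: 4 tests; executive: 7; processing speed: 4), and
the three domain compounds averaged into the overall compound. A domain
compound is computed from the remaining tests when exactly one is missing
and is absent when more than one is missing; this rule is applied
uniformly to all three domains (it is naturally stated for the domain
where missingness bites hardest, but there is no reason to privilege one
domain). A missing domain makes the overall compound missing. Education is
encoded ordinally 1/2/3 (low/middle/high).

## Association models

OLS with a decline compound as outcome and one leakage measure as
predictor; the adjusted model adds age, sex (0/1), education (ordinal),
relative WMH volume and relative brain volume. The reported B is
standardized by z-scoring outcome and leakage predictor before the fit
(covariates on native scale); in the univariable case B equals the Pearson
correlation. An option standardizes all continuous regressors; the exact
convention behind published standardized coefficients is generally not
recoverable, so both are offered and the default documented. CIs and
two-sided p-values come from the t-distribution of the OLS coefficient;
significance at p < 0.05 with no multiplicity correction by default
(Benjamini–Hochberg available behind a flag). Complete-case analysis
throughout; rank deficiency is detected on unit-norm columns so covariate
scale can neither mask nor fake collinearity, and grid-cell failures are
recorded in-table without aborting the grid.

A calibration subtlety the test suite makes explicit: when the synthetic
effect is injected on the sample-standardized predictor and the outcome is
itself a sample z-score, the t-interval around the standardized B is
conservative (measured ~98–99% coverage), because the "truth" holds
exactly conditional on the sample. The nominal 95% guarantee applies in
the classical regime — latent-scale outcome, fixed design, no outcome
rescaling — where measured coverage is ~95%. Both facts are checked.

## Synthetic cohort

One row per patient: covariates (age ~ N(67, 12²); sex Bernoulli 0.59;
education 1/2/3 with probabilities 0.47/0.35/0.18; relative WMH volume
~ N(0.014, 0.006²) clipped at 0; relative brain volume ~ N(0.675, 0.05²)),
baseline leakage measures drawn per region from the cohort-scale
distributions (v_L: 32(16), 39(19), 18(11), 30(19) %; mean Ki: 3.1(1.6),
3.4(2.0), 2.3(1.2), 3.1(2.0) ×10⁻⁴ min⁻¹ for NAWM/WMH/CGM/DGM), and a
15-test battery at two time points. The latent decline of each domain is a
linear function of z-scored leakage measures (configurable effects per
(region, measure, domain)) plus z-scored covariate effects plus Gaussian
noise (default SD 0.5 z-units at the domain level and 0.5 at the test
level); each test realizes its domain's latent decline on its own raw
scale, inverted-scale tests by increasing at follow-up. Latent declines
are emitted as ground-truth columns so recovery can be checked exactly.
Follow-up scores go missing independently at the configured rate. The
cohort generator and the leakage sampler use decoupled random streams, so
equal seeds cannot induce spurious covariate–leakage correlation.

## What the generators do not emulate

No k-space or parallel-imaging (SENSE) simulation, no motion, no
partial-volume effects, no segmentation errors: masks are ground truth by
construction, and the fast and slow sequences share one voxel grid (a
config flag can down-sample the fast series to mimic its coarser
resolution). The cohort's decline model is linear by construction with
normal noise. Passing tests therefore demonstrate correctness of the
computational chain and its statistical behavior under the stated models —
not robustness to registration error, motion, non-Gaussian physiology, or
model misspecification in real patients.

## Problem sizes

Defaults were chosen so the full pipeline runs in seconds: phantom grid
32×32×10 (10,240 voxels, 8,704 of them tissue), 29 + 45 volumes, cohorts
of 51 (pipeline default) to 400 (recovery studies) patients, 100 replicate
cohorts for coverage checks, 10⁵ draws for histogram null checks. All are
configuration, not code.

## Known limitations

- The Patlak model ignores backflux and is fit after the first pass only;
  rates far above the cSVD regime (≫10⁻³ min⁻¹) violate its assumptions
  and are out of scope.
- mean Ki after noise correction estimates the detectable rate (see
  above); comparing it across cohorts assumes comparable noise levels.
- The VIF is noiseless in form (parametric); patient input functions carry
  dispersion and partial-volume effects the phantom does not model.
- Histogram measures depend (boundedly) on bin width; the default is
  documented and configurable, and the discretization bound is tested.
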