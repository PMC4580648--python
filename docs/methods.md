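# Methods

This note documents the models, estimators and numerical choices behind
`swaysync`, and what the synthetic study can and cannot show about real
recordings.

## Problem setting

Two people stand face to face for 60 s while their head positions are
tracked at 200 Hz along the anterior-posterior (AP) and left-right (LR)
axes. Vision is manipulated per trial: both partners sighted (OO), one
blindfolded (BO: participant x blindfolded; OB: participant y
blindfolded), or both (BB), at a Near or Far interpersonal distance.
Three questions drive the analysis chain:

1. **Do the two sway series synchronize, and with what time lag?**
   (lagged cross-correlation)
2. **Who influences whom, and how much?** (directed noise-contribution
   ratios from a bivariate AR model)
3. **Does a linear feedback system with the fitted coefficients
   reproduce the lag structure?** (white-noise-driven simulation)

## Signal conditioning

Two parallel paths, chosen to serve their consumers:

* **Correlation path (200 Hz).** Linear detrend (least-squares line
  subtracted), then a full-length Hanning taper. The correlation's
  means and SDs are computed on the tapered series itself, keeping the
  statistic self-consistent; the alternative (normalizing with
  pre-taper statistics) is not exposed because it mixes two different
  signals in one formula.
* **AR path (5 Hz).** 40-fold decimation with a 30th-order FIR low-pass
  at the post-decimation Nyquist, then linear detrend. The FIR filter
  is applied forward-backward (zero-phase) so decimation cannot shift
  lag structure; subsampling starts at index 0 and output length is
  `ceil(n/40)`. A 60 s trial becomes 300 samples.

## Lagged cross-correlation

For series x, y of length N (after conditioning),

    R_xy(tau) = 1/(N-1) * sum_t (x(t+tau) - x̄)(y(t) - ȳ) / (s_x s_y)

summed over the overlapping range, with sample SDs (N−1 denominator)
over the full series. The implementation evaluates the lagged sums by
FFT correlation, which agrees with the direct sum to ~1e-12 (tested).
R(0) = 1 when x = y; values can exceed the [−1, 1] envelope only by
numerical noise.

**Sign convention.** Pairing x(t+tau) with y(t) means a peak at
positive tau indicates y's fluctuations *precede* x's. This puts the
blindfolded partner's documented lead at negative lags in BO (x
blindfolded) and positive in OB, which is the convention used in every
table this package writes.

**Peak detection.** The synchronization lag is the lag of the maximum
*positive* correlation within ±1 s (an option switches to maximum
magnitude). Exact ties break toward the smallest |lag|, then toward the
negative lag — an arbitrary but fixed rule, so results are
deterministic.

## Bivariate AR model and order

At 5 Hz, each channel is regressed on the joint p-lag history of both
channels (no intercept; inputs are detrended):

    x(t) = sum a_i x(t-i) + sum b_i y(t-i) + u_x(t)
    y(t) = sum c_i x(t-i) + sum d_i y(t-i) + u_y(t)

by per-equation OLS over t = p+1..N. Innovation variances are
RSS/(n_eff − 2p). AIC is defined as

    AIC(p) = n_eff * ln det(Sigma_ML(p)) + 2 * 4p

with all candidate orders fit on a common effective sample (first
max_order points withheld) so the criterion is comparable across p.
Order selection is a diagnostic; production analyses fix **p = 3** so
that data-driven order choice cannot leak into the statistical
comparisons. Estimation is per trial; condition-level quantities are
averages of per-trial results, keeping trials independent for
inference. Residual whiteness (Ljung-Box per channel) and lag-0
residual cross-correlation are checked because the causality
decomposition below assumes white, mutually independent innovations.

## Noise contribution ratio (Akaike causality)

The AR transfer matrix is H(f) = (I − Σ A_i e^{−j2πf iΔt})^{−1} with
entries [[α, β], [γ, δ]]; the implementation inverts the 2×2 matrix
directly and carries an independent impulse-response-summation route
used in tests (agreement < 1e−8). With independent innovations, x's
power at f splits exactly into |α|²σ_ux² (own noise) and |β|²σ_uy²
(partner's noise), and

    NCR_y→x(f) = |β|²σ_uy² / (|α|²σ_ux² + |β|²σ_uy²)  ∈ [0, 1],

symmetrically for x→y. NCR is evaluated on 512 uniform frequencies on
[0, fs/2] (grid error at AR(3) smoothness is < 0.1 percentage points
against a 4096-point grid, tested), integrated by the trapezoidal rule
and normalized by the Nyquist bandwidth, ×100:

    ΣNCR = 100/(fs/2) * ∫ NCR(f) df   ∈ [0, 100] %.

The bandwidth normalization keeps ΣNCR comparable across sampling
rates; a constant NCR(f) = c yields 100c %.

## Inferential statistics

* **Lag tests** (pair level, n = 22): OO per-pair mean lags vs 0 ms by
  one-sample t-test; BO and OB vs OO by paired t-tests with Bonferroni
  ×2. Raw and corrected p-values are always reported together.
* **Influence-asymmetry regression** (pair level): Y = B0 + B1·X with
  Y the pair's OO synchronization lag and X the co-oriented influence
  difference X = ΣNCR(y→x) − ΣNCR(x→y). Positive X means x is the more
  influenced partner, hence expected to trail (positive lag), so the
  reciprocal-feedback account predicts B1 > 0. t-tests on B0, B1 with
  n−2 df.
* **ΣNCR ANOVA** (participant level, n = 44): each participant
  contributes the influence *received* in all 8 SENDER × RECEIVER ×
  DISTANCE cells (SENDER = partner's visual state, RECEIVER = own
  state). All factors have 2 levels, so each repeated-measures effect
  reduces exactly to a one-sample t-test on the per-participant
  contrast score: F = t² with df (1, n−1), η_p² = t²/(t² + n − 1). No
  sphericity correction is needed with 2-level factors. The
  implementation is cross-checked against pingouin's two-factor
  rm-ANOVA on the follow-up designs.

## Simulation study

Fitted Near-distance AR models (OO, BO, OB; one per trial) are driven
with fresh standard-normal white noise — unit SD by design, not the
estimated residual SDs, to probe the feedback structure under a
standardized input. Zero initial state, 500-sample burn-in discarded.
Each pair × condition is simulated 40 times at trial length (300
samples, 5 Hz), repetitions cycling over the four per-trial models; a
single root seed expands deterministically to per-repetition seeds.
Simulated dyads then pass through the identical correlation/peak
analysis. At 5 Hz a single trial resolves lag only to 200 ms;
sub-resolution mean lags arise from averaging, as in the behavioral
analysis. BB is not simulated (no peak to locate in uncoupled dyads).

## Synthetic-data generator

The generator is the test bed: it produces dyads with *known* coupling
so every stage can be checked against ground truth.

* Dynamics: stable bivariate AR(3) at 5 Hz. A condition's lag-1 matrix
  is [[s, b], [c, s]] with self-strength s = 0.5 and coupling 0.3 on
  the open partner's incoming path (OO: b = c; BO: b = 0; OB: c = 0;
  BB: b = c = 0); lags 2 and 3 are geometrically decayed copies
  (ratio −0.45), giving every lag an identifiable coefficient while
  keeping the sway spectrum low-frequency dominated. Every emitted set
  is verified stable (companion spectral radius < 1) and unstable
  requests are rejected with the computed radius.
* Distance: a multiplicative coupling scale (Near 1.0, Far 0.4). The
  generative mechanism behind weaker influence at distance is unknown;
  a monotone knob is the minimal assumption.
* Path to 200 Hz: 500-sample burn-in discarded, band-limited polyphase
  upsampling ×40 (so the decimation stage approximately inverts it),
  then a per-channel random linear trend (slope uniform in ±0.02 mm/s)
  and white measurement noise (SD 0.05 mm) that the preprocessing must
  remove.
* Amplitudes: unit-SD innovations give mm-scale sway (detrended
  variance ≈ 1.2–1.4 mm²). Published variance tables for this paradigm
  are image-only, so amplitudes are plausible rather than matched;
  every analysis in the chain is scale-invariant, so this affects
  realism, not correctness.
* Determinism: per-trial seeds derive from the study seed and the
  trial's design coordinates, so any subset regenerates bit-identically.

**What passing tests show — and don't.** The generator is the model
family the estimator assumes (linear, Gaussian, stationary after
detrending). Passing recovery/calibration tests therefore validates the
estimation and inference machinery, not the adequacy of a linear AR
description for real postural sway (nonlinearities, nonstationarity
within trials, and true sway spectra are outside the generator).

## Numerical and design choices

* Burn-in 500 samples everywhere a recursion starts from zero state.
* FFT-based correlation only because it reproduces the direct
  overlapping-range sum to ~1e-12; the normalization of the printed
  formula is never replaced by a convolution-theorem variant.
* Rank-deficient AR design matrices (e.g. x ≡ y) raise immediately
  rather than falling back to a pseudoinverse.
* Degenerate ANOVA contrasts (zero between-subject variance) return
  F = 0, p = 1 when the mean contrast is zero, F = ∞, p = 0 otherwise.
* Coordinate frames: both participants are analyzed in the shared
  laboratory frame. Face-to-face geometry flips the egocentric sense of
  AP/LR; a per-participant sign flip can be applied upstream if an
  egocentric convention is wanted.
* MAT ingestion never guesses a layout: without an explicit variable
  mapping it fails with a full introspection report.

## Study sizes used by the shipped drivers

The numbered analysis scripts and the acceptance script run the full
synthetic design (22 pairs × 2 distances × 4 conditions × 4 trials,
AP axis; 40 simulation repetitions per pair and condition), the
calibration batteries use 100–1000 replicates per check, and parameter
recovery uses 10⁴-sample realizations — sizes at which the Monte-Carlo
error of every reported rate is well below the decision thresholds
applied to it.

## Known limitations

* Bivariate only: no conditional (multi-node) causality, no partial
  directed coherence; this is the intended scope.
* ΣNCR's absolute level depends on the bandwidth-normalization
  convention; comparisons across studies should use orderings and
  differences, not absolute percentages.
* The 5 Hz simulation cannot resolve single-trial lags finer than
  200 ms; only averaged lags are meaningful at sub-sample scale.
* Real recordings may violate innovation independence (shared
  mechanical or visual drive); the whiteness/independence diagnostics
  gate the decomposition but cannot repair it.
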