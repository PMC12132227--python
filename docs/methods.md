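# Methods

## Measurement model

A PAM protocol is a list of inter-flash intervals with a light/dark phase
partition. Time zero is actinic-light onset; flash *k* occurs at the
cumulative sum of the first *k* intervals, and F<sub>o</sub>/F<sub>m</sub>
are taken before illumination, outside the flash list. Each phase segment
carries a local clock that restarts at the phase transition; for dark
segments, light-off is taken to coincide with the final light-phase flash,
so relaxation is fit against time since darkness.

Phase membership is defined by the declared flash partition
(n_light/n_dark per cycle), not by comparing cumulative time to the nominal
phase duration. The two bundled presets illustrate why: in `crop_default`
the light-phase intervals sum to 675 s although the nominal light period is
10 min; the 13-light/6-dark partition is the operational definition and the
nominal durations are carried only as metadata. In
`arabidopsis_fluctuating` the printed intervals partition exactly into
180 s light + 120 s dark per cycle.

NPQ per flash is the Stern-Volmer ratio F<sub>m</sub>/F<sub>m</sub>′ − 1.
Marginally negative NPQ (F<sub>m</sub>′ slightly above F<sub>m</sub>, a real
artifact) is retained rather than clipped — clipping biases fits near zero —
and screened later by QC. Similarly, a trace with F<sub>m</sub> ≤
F<sub>o</sub> is loaded with a warning rather than rejected, so the Fv/Fm QC
rule can flag it.

## Kinetics models and fitting

* Induction (light): NPQ(t) = A·t/(K + t), and alternatively
  A·(1 − e<sup>−t/τ</sup>) for the induction time constant τ. Which form a
  study reports is a modelling choice; both are always fit and reported.
* Relaxation (dark): NPQ(t′) = N₀ − A_D·t′/(K_D + t′). N₀ starts at the
  observed NPQ at light-off and is fit freely; the physical constraint
  0 ≤ A_D ≤ N₀ is imposed by parameterizing A_D = frac·N₀, frac ∈ [0, 1].

Bounds: amplitudes (0, 20], time parameters (0, 10⁴] s — NPQ in this assay
is O(0.1–4), and the bounds stop runaway asymptotes on short series.
Optimization is bounded trust-region least squares with deterministic
multi-start: 5 starts from a log-spaced grid on the time parameter spanning
half the first positive sample time to twice the last, crossed with the
amplitude initialized at the last observed value; lowest RSS wins, ties
broken by the smallest time constant. There is no randomness in fitting.

Degenerate relaxation data (flat or increasing series) sit on a parameter
ridge: a tiny A_D with a huge K_D traces the same flat line as A_D = 0. A
parsimony tie-break collapses that ridge — if a flat line at the mean
matches the optimizer RSS to within 1e-12, the fit reports A_D = 0 (K_D
undefined) and flags `amplitude_at_lower_bound`; an increasing series
additionally reports non-convergence, since the model family excludes it.

Slope traits are the fitted curve's derivative at t = 0 (A/K), not a finite
difference of the first two points — robust to flash spacing. NPQ_max and
NPQ_end are defined as *observed* last light/dark values (an alternative
reading as the fitted induction maximum exists; the observed-value
definition wins because it stays meaningful when fits fail). Goodness of
fit is the coefficient of determination 1 − SS_res/SS_tot, which may be
negative and is undefined (flagged None) on zero-variance data.

Fluctuating-light protocols are fit cycle by cycle on each segment's local
clock; cycles with too few points keep their observed traits with null
fitted traits.

## Synthetic data

The generator emulates the measurement chain, not the photophysics: ground
truth is drawn from the same hyperbolic/exponential family the fitter
assumes, inverted through F<sub>m</sub>′ = F<sub>m</sub>/(1 + NPQ), with
multiplicative Gaussian noise on the fluorescence channel (F<sub>m</sub>′,
F<sub>o</sub>, F<sub>m</sub> independently; default sd 0.03, a calibration
choice — no instrument noise magnitude is established here). Noise on the
fluorescence scale makes NPQ noise heteroscedastic, as real Stern-Volmer
ratios are. F<sub>s</sub> is emitted at a fixed 0.6·F<sub>m</sub>′ dummy
proportionality; nothing downstream consumes it. What the generator does
*not* model: qE/qZ/ΔpH mechanism, leaf optics, chlorophyll content, pulse
width — so passing tests demonstrate correct recovery of the assumed model
family under realistic noise, not robustness to model misspecification in
real leaves.

Defaults (one set, chosen once as typical of crop NPQ curves at
1000–2000 µmol m⁻² s⁻¹): A_L = 2.5, K_L = 90 s, τ = 60 s, A_D = 1.8,
K_D = 120 s, F<sub>o</sub> = 0.5, F<sub>m</sub> = 3.0 (instrument units).
N₀ defaults to the induction value at light-off, keeping the curve
continuous at the phase transition; an explicit N₀ overrides it.

Fluctuating light: incomplete dark relaxation leaves residual ρ = N₀ −
A_D·T_D/(K_D + T_D); the carried offset at the start of cycle *c* is
(g<sup>c</sup> − 1)·ρ with g = `residual_gain` ≥ 1, so the dark-end value
of cycle *c* is g<sup>c</sup>·ρ: g = 1 gives identical cycles with no
carry-over, g > 1 strictly increasing dark-end residuals.

Factorial studies apply multiplicative genotype and treatment effects to
the kinetic parameters, then lognormal replicate scatter (log-sd 0.05 by
default) and measurement noise; every realized parameter is recorded in a
truth table for recovery testing. Paired leaf-disc/whole-plant simulations
share one truth with independent noise; the approach bias multiplies the
disc's NPQ scale, so the concordance slope tends to the bias value. The
concordance experiment averages 8 replicates per approach per time point
before regressing, matching how such comparisons are made in practice —
per-trace multiplicative F<sub>m</sub> noise scales a whole trace's
(1 + NPQ) axis, and only replicate averaging removes that slope jitter.

Plate rendering places each trace as a filled disc (radius 10 px, area
~317 px, within the ~320-px leaf-disc ROI regime) on a regular 8×12 grid;
frame 0/1 are F<sub>o</sub>/F<sub>m</sub>, frames 2+ the flashes. The mean
disc intensity equals the reading exactly at zero pixel noise, so
render → extract is an identity up to float rounding of the mean (~1e-14).

## QC

Defaults standing in for a study-specific integrity procedure, all
config-exposed: flag when goodness of fit < 0.90 in either phase, any fit
non-converged, Fv/Fm outside (0, 0.90], any NPQ < −0.05, or the induction
asymptote beyond 3·MAD of its genotype×treatment cohort median. Every
triggered rule is listed per sample; nothing is silently dropped.

## Statistics

Brown-Forsythe is the median-centered Levene test; Shapiro-Wilk runs on
group-mean-centered residuals; failing either at α = 0.05 recommends a
natural-log transform (natural log chosen; any log is equivalent up to
scale), refused with a warning when values are not strictly positive.
ANOVA uses Type II sums of squares by default (replicate counts in such
experiments are typically unbalanced; Type III is available via config).
Dunnett comparisons are two-sided, with adjusted p-values from the
equicorrelated multivariate-t implied by the shared control
(`scipy.stats.dunnett`); the quasi-Monte-Carlo integration of that
distribution is seeded for reproducibility, and the implementation is
validated against simulated family-wise error in the test suite. Pairwise
t-tests are pooled-variance with a Welch fallback when Brown-Forsythe
rejects. Concordance is OLS of disc on whole-plant NPQ (axis order is a
convention; the near-identity regime makes the choice immaterial),
reporting slope, intercept, adjusted R² and RMSE = √(mean squared
residual).

## Problem sizes

Monte-Carlo checks use 200 simulations for parameter recovery and
concordance, 500 for QC flag rates, and 10,000 for Dunnett/t calibration —
sizes at which the binomial standard error is comfortably inside the
tolerances being checked. Parameter recovery is assessed as the median
relative error across simulations (robust to the heavy-tailed K estimates
a 6-point dark phase produces).

## Known limitations

* The trait panel covers the six fitted/observed kinetics traits plus
  Fv/Fm; instrument-derived parameters with no defining formula here
  (NPQ_T, ECSt, gH⁺, LEF, PSI redox fractions) are out of scope.
* No joint multi-sample or hierarchical fitting; no confidence intervals
  on kinetic parameters.
* Plate extraction assumes fixed circular ROIs from the layout config;
  there is no disc detection or image registration.
* The generator's noise model is a single multiplicative term; real
  imagers add pixel-level and illumination-gradient structure that is only
  represented in the plate renderer's optional pixel noise.
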