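# Methods

## Data model and preprocessing

A trial CSV holds one row per dynamometer sample: athlete, muscle action
(extension/flexion), contraction mode (concentric/eccentric), repetition
number, knee flexion angle (0° = full extension, 90° = deep flexion),
signed angular velocity (°/s) and moment of force (N·m). Torques are assumed
gravity-corrected upstream. Validation drops and counts rows with angles
outside [0°, 90°], non-finite torques, unknown labels or unparseable cells;
a missing column is a hard error.

Preprocessing mirrors standard isokinetic practice:

- **Truly-isokinetic filtering** keeps samples with ``||v| − 60| ≤ tol``;
  the tolerance defaults to ±6°/s (10% of the target). Speeds are compared
  because flexion and extension phases carry opposite signs in raw exports.
- **Best repetition**: within each (athlete, action, mode) group the
  repetition with the greatest peak torque is kept; ties go to the lower
  repetition number. "Best" is not standardized in the field; maximal peak
  torque is the common operationalization and gives the selection a
  well-defined truth in simulation.
- **Axis conventions**: all modelling and ratio pairing happens on the
  anatomical flexion-angle axis. Extension results are *displayed* on the
  rescaled extension-progress axis, 90° − angle, an involution that puts 0°
  at the start of the extension effort.

## The hierarchical GAM

For one (action, mode) dataset,

    y_ij = β₀ + f(x_ij) + b₀ᵢ + fᵢ(x_ij) + ε_ij,   ε_ij ~ N(0, σ²),

with a single common smoother f and athlete-level deviations. Smooths are
P-splines: cubic B-spline bases on uniform knots over the fixed 0–90° domain
(boundary knots degree-replicated), penalized by second-order coefficient
differences. Eigendecomposing the penalty S = UΛUᵀ splits each smooth into
an unpenalized polynomial part X₀ = B·U₀ (dimension = penalty order, here 2)
and penalized columns Z = B·U₊Λ₊^(−1/2) whose coefficients act as i.i.d.
zero-mean Gaussian random effects; a unit ridge on Z-coefficients with
variance τ² reproduces the smoothing penalty with λ = 1/τ². Defaults:
K = 10 basis functions for the population smooth, K_ind = 6 for the
per-athlete deviations (deviations are deliberately cheaper than the common
shape), degree 3, penalty order 2 — all configurable, and results should be
read with K in mind since no canonical basis dimension exists for these
curves.

The fixed block is [1, X₀]; the constant direction is functionally shared
between the global intercept and the penalty null space, so β₀ alone is not
identified, but the proper N(0, 10⁶) prior keeps the joint posterior proper
and all fitted values and predicted curves are invariant to the unidentified
direction. Random blocks: per-athlete intercepts (variance σ_b²) and
per-athlete Z-blocks sharing one τ_ind². With a single athlete the hierarchy
collapses to a population smoother with a warning.

**Sampler.** The Gaussian response makes every conditional conjugate, so a
blocked Gibbs sampler is exact in distribution: (i) one joint Gaussian draw
of all coefficients from the penalized normal equations
(XᵀX/σ² + P)θ = Xᵀy/σ², sampled via the Cholesky factor of the precision;
(ii) inverse-gamma updates of τ_pop², σ_b², τ_ind² given their coefficient
blocks; (iii) an inverse-gamma update of σ² from the residuals.
"Uninformative" priors are operationalized as inverse-gamma(0.001, 0.001) on
every variance and N(0, 10⁶) on unpenalized fixed coefficients. Defaults are
4 chains × 2000 iterations with 1000 warmup; the sampler mixes fast enough
that the replicated simulation studies in the test-suite use single chains
of 700–1200 iterations. Chains are seeded through
``numpy.random.default_rng([seed, chain])`` and runs are bit-reproducible.
Convergence reporting (split-R̂, bulk ESS) delegates to arviz.

Pointwise log-likelihoods log N(y_ij | μ_ij⁽ˢ⁾, σ⁽ˢ⁾) are stored per draw
for WAIC: lppd computed with log-sum-exp, p_waic as the *sample* variance of
the log-likelihood over draws (ddof = 1), waic = −2(lppd − p_waic). arviz
uses the population variance (ddof = 0) for p_waic, which the cross-check
test accounts for; at practical draw counts the difference is O(1/S). The
comparison surface is the intercept-only versus intercept+smooth-deviation
pair, with the elpd difference and its standard error
√(n·var(elpd_iᴬ − elpd_iᴮ)) reported.

## Posterior outputs

Population curves evaluate β₀⁽ˢ⁾ + f⁽ˢ⁾ on an angle grid per draw, random
effects marginalized at zero; a flag instead draws a fresh athlete's
intercept and smooth deviation per iteration for new-individual predictive
bands. Default grids use a 1° step restricted to the fit's observed
(truly-isokinetic) angle span — outside it the curve is informed by the
prior alone, and extrapolation beyond the basis domain raises. Bands are
pointwise equal-tailed 95% percentile intervals.

Ratio curves pair numerator and denominator draws iteration-by-iteration
across the two independent fits (valid because the posteriors are
independent; unequal draw counts are subsampled with a fixed seed). Grid
points where the denominator's posterior mean falls below 1 N·m are masked
to prevent blow-up near the ends of the range of motion. Point-of-equality
crossings are linear interpolations of the posterior-mean curve through 1.0
(exact grid hits reported once); extrema are sign changes of first
differences with plateau midpoints, endpoints excluded, masked stretches
splitting the scan.

## The synthetic generator

The generator emulates the target study design: 30 athletes, four
action-mode datasets, five repetitions sweeping 0–90° on a 1° grid with a
trapezoidal velocity profile (10% ramp at each end, exact 60°/s plateau, so
the constant-velocity fraction is known exactly). Quadriceps curves
(concentric extension: 190 N·m peak at 60°; eccentric flexion: 210 N·m at
55°) are floor-plus-asymmetric-Gaussian bumps; the hamstring curves are
constructed as planted-ratio × quadriceps so the implied ratio features are
exact: the extension ratio 1 + 0.35·tanh((θ−50)/25) crosses 1.0 exactly at
flexion 50° (40° of extension progress), and the flexion ratio (two Gaussian
bumps at 20° and 80° over a slight linear tilt, offset so the minimum is
exactly 0.54 near 54°) stays below 1.0 everywhere.

Athlete effects: intercepts N(0, σ_b²) with σ_b = 8 N·m; smooth deviations
drawn from the same P-spline family the model fits (τ_ind = 5 N·m on the
penalized coefficients; a Fourier variant exists to study misspecification);
repetition effects are scalar offsets N(0, 3²) so "best repetition" has a
planted truth (the largest offset); residual noise is i.i.d. N(0, 6²).
Values not fixed by the emulated design (τ_ind, σ_rep, curve floors and
widths) were chosen once as plausible for adolescent athletes and are
config fields.

**What the generator does not emulate**: velocity jitter (profiles are
deterministic trapezoids, so filtering truth is exact), torque–velocity
coupling during ramps, fatigue across repetitions, autocorrelated residuals
along the sweep, and body-size scaling. Passing recovery tests therefore
show sampler and pipeline correctness under the assumed data-generating
process, not robustness to these real-data features. In particular the model
assumes i.i.d. residuals although dynamometer sweeps are time series;
residual autocorrelation is a known limitation, not an implemented feature.

**The estimand under best-repetition selection.** Selecting each athlete's
maximal-effort repetition shifts the observed series upward by roughly the
expected maximum of the repetition offsets (≈ +3.5 N·m at σ_rep = 3, R = 5).
The fitted population curve estimates this maximal-effort curve, so recovery
is scored against the planted curve plus the realized mean offset of the
repetitions actually selected — the ground-truth record stores every
repetition's offset to make that exact.

## Numerical choices

- Penalty null-space eigenvalue threshold: max(Λ)·1e−10; a mismatch between
  detected null dimension and the penalty order is an error.
- The heavy-smoothing limit of a P-spline fit is the least-squares fit on
  the X₀ columns (coefficient sequences linear in index), which differs
  slightly from a straight line in x near replicated boundary knots.
- The trapezoid plateau is snapped exactly to the target velocity so the
  constant-velocity fraction is well defined despite float division.
- Fit serialization writes draws as CSV at 17 significant digits (exact
  float64 round-trip) with a JSON sidecar of spec/seed/priors.
- Replicated studies in tests and the acceptance script use single chains of
  700–1200 iterations (250–400 warmup); the conjugate sampler's effective
  sample sizes make longer defaults unnecessary for these checks.

## Known limitations

- i.i.d. residuals (above); Gaussian response only; no tensor-product or
  cyclic smooths; no adaptive knots.
- β₀ is only jointly identified with the smooth's constant direction
  (harmless for curves, visible in raw coefficient traces).
- Whether published ratio bands include individual-level variance is
  ambiguous in practice; bands here are population-level by default, with
  ``include_random_variance`` for new-athlete bands.
- The flexion-ratio trough is nearly flat, so its *angle* is weakly
  determined by construction; the trough *value* is the stable quantity and
  both are reported.
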