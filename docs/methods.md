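# Methods

This note records the model conventions, parameter defaults, numerical
choices, and known limitations of `qcmfit`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus and design representation

Stimuli are bipolar temporal modulations in the LM cone-contrast plane,
stored by their positive arm: chromatic direction in degrees
(counterclockwise from +L, canonical in [−180, 180)) and vector-length
contrast as a dimensionless fraction. The negative arm is implied by
bipolar symmetry and never stored. The 12 Hz carrier is not simulated
sample-by-sample: the model operates on block-level responses, so a block
is represented by its envelope. The 500 ms half-cosine on/off ramps are a
sub-TR effect and are ignored in the boxcars.

The default protocol constants: 12 s blocks, 288 s runs of 24 blocks
(20 stimulus + 4 background), TR = 0.8 s (360 TRs/run), 10 runs/session,
two sessions per measurement set with disjoint direction groups
({−45, 0, 45, 90}° and {−22.5, 22.5, 67.5, 112.5}°), two measurement
sets. Per-direction maximum contrasts reflect device-gamut limits
(0.12, 0.085, 0.14, 0.20, 0.60, 0.40, 0.22, 0.13 in the direction order
above after interleaving); each direction carries a five-level ladder at
relative contrasts 1, 1/2, 1/4, 1/8, 1/16 of its maximum.
Pseudorandomization of block order is a uniform seeded shuffle subject to
each direction/contrast pair appearing exactly once per run; background
block positions are unconstrained (their placement is not otherwise
specified by the protocol).

GLM design matrices carry one convolved-boxcar column per unique
condition plus a single intercept-like baseline column of ones shared
across concatenated runs; background blocks carry no regressor of their
own. Concatenation merges like condition labels and convolves each run
independently, so no hemodynamic bleed crosses run boundaries.

## The quadratic color model

Equivalent contrast uses the normalized isoresponse ellipse: major axis
(least-sensitive direction) at angle φ ∈ [0, 180) with unit length, minor
axis ratio r ∈ (0, 1]. With R the rotation taking the major axis onto the
first coordinate, Q = Rᵀ diag(1, 1/r²) R and e(c) = √(cᵀQc). e is
homogeneous of degree 1, symmetric under c → −c, and equals ‖c‖ along the
major axis and ‖c‖/r along the minor axis. Inputs must lie in the LM
plane (S-cone contrast exactly 0).

The nonlinearity is the conventional four-parameter Naka–Rushton form
R(e) = offset + amplitude · eⁿ/(eⁿ + σⁿ) — amplitude is the response
range, σ the semi-saturation equivalent contrast, n the slope exponent,
offset the response at zero equivalent contrast. Other normalizations of
the ellipse/nonlinearity pair are observationally equivalent up to
reparameterization; this convention makes r directly interpretable as a
relative sensitivity and σ as an equivalent contrast.

The neural time course is piecewise constant (R(e) during stimulus
blocks, R(0) during background), and the BOLD prediction is its causal
convolution with the HRF, truncated to run length, per run.

### Fitting

`fit_qcm` minimizes the RMSE between the measured and predicted series
over the six parameters with L-BFGS-B under bounds: angle [0, 180], ratio
(0.001, 1], amplitude (0, 10], σ (0.001, 5], exponent (0.1, 10], offset
[−5, 5]. Because block boxcars tile each run, the prediction is linear in
the per-condition responses; the per-condition convolved boxcars are
precomputed once, so each objective evaluation is a small matrix-vector
product. The RMSE surface is 180°-periodic in angle, so the optimizer
multistarts from eight angles tiling [0, 180) plus one seeded jittered
start; the best minimum wins. The returned angle is canonicalized to
[0, 180). If the fitted ratio reaches 1 (a circular contour) the angle is
unidentifiable and is flagged rather than reported. An all-constant input
series is returned as a flagged degenerate fit. `fit_qcm_locked` fixes
the angle (5 free parameters). R² is the coefficient of determination
about the mean of the measured series, for comparability across models;
censored timepoints, when a mask is supplied, are excluded.

## Hemodynamics

The HRF basis is the SPM-style informed set — canonical double-gamma
(peak delay 6 s, undershoot delay 16 s, dispersion 1 s, undershoot ratio
1/6) plus its temporal and dispersion derivatives (central finite
differences), Gram–Schmidt orthogonalized and unit-norm, sampled at TR
over 32 s. This is a stand-in basis with the same role as a 3-component
empirical flexible basis; externally supplied basis shapes can be loaded
from TSV.

Subject-level HRF estimation is alternating least squares: with the
kernel fixed, the GLM betas are the OLS solution; with the betas fixed,
the three basis weights are again a linear least-squares problem (the
prediction is linear in the kernel). Iteration stops when the RMSE
improves by less than 1e-8 (at most 100 outer iterations). The
kernel/beta scale ambiguity is resolved by unit-peak normalization of the
returned kernel; the procedure involves no randomness and is invariant to
rescaling the input series.

## Benchmark GLM and the constrained Naka–Rushton family

The GLM is plain OLS via an SVD-backed solver (minimum-norm solution and
a warning with the condition number when rank-deficient; no prewhitening,
matching the benchmark it reproduces). Grouping condition betas by
direction, with the baseline beta subtracted, yields eight five-point
contrast response functions.

The Naka–Rushton CRF family replaces per-condition betas with a monotone
Naka–Rushton CRF per direction. The semi-saturation is always free per
direction, the offset always shared; amplitude and exponent are shared or
free per the family spec (parameter counts for 8 directions: 25 with all
but the offset free, down to 11 fully locked). Fitting uses the same
bounded-minimizer conventions as the QCM, on the time course by default;
a flag fits in beta space instead, since either reading of the procedure
is defensible. Monotonicity holds by construction (positive amplitude).

## Preprocessing

Fixed operator order: percent signal change → nuisance regression →
motion censoring → 5th-order polynomial detrend → ROI median. Motion
"relative" estimates are frame-to-frame differences; absolute input is
differenced internally, and a switch accepts degree rotations. Framewise
displacement converts rotations to arc length on a 50 mm sphere and takes
the L2 norm of the six millimeter displacements (the norm makes rotation
sign irrelevant). Censoring drops the 3-TR window centered on each
FD > 0.5 mm exceedance, clipped at run edges; it is mask propagation, not
interpolation — the detrend fits on kept timepoints only (evaluated on
all), and downstream R²/RMSE can exclude the mask.

## Evaluation machinery

Leave-runs-out cross-validation randomly pairs session-1 and session-2
runs one-to-one with a seeded permutation; each of the 10 folds holds out
one pair, fits on the remaining 18 runs, and scores R² on the held-out
series (using the held-out series' own mean in the total sum of squares).
Leave-session-out fitting exploits the disjoint direction groups to test
generalization to unmeasured directions. Bootstrap CIs resample runs with
replacement within each session independently (keeping every direction
represented), refit, and take the 16th/84th percentiles (200 iterations).
The residual diagnostic averages measured-minus-predicted over the
closed-open TR window [onset+4, onset+14) per block, then over blocks
within a direction. The eccentricity analysis is iteratively reweighted
least squares with the Tukey bisquare (c = 4.685); optional weighting by
vertex R² is available but off by default. Δ(0°–20°) = |slope| × 20.

Percentile intervals are mildly anticonservative at small run counts: at
10 runs/session the within-session bootstrap shrinks the sd by roughly
√(9/10), and with 200 replicates the empirical 68% coverage is near 0.64.
The coverage test therefore evaluates the machinery at 50 runs/session
(400 outer replicates), where the method operates in its asymptotic
regime; at protocol run counts the intervals should be read as slightly
narrow.

## Synthetic data

The generator produces exactly the structure the analysis assumes: the
full block protocol, a QCM ground truth, and additive white (or AR(1))
noise, fully determined by (config, seed). The default truth — angle 45°,
ratio 0.2, amplitude 2, σ = 1, n = 1.5, offset 0 — places the strongest
stimuli (equivalent contrast ≈ 0.6) well below saturation, the fitted
regime the model targets; it is a simulation default, not a claim about
any dataset. The noise sd (default 1.8 in percent-signal-change units)
was calibrated once by bisection so that the median per-run GLM R² is
≈ 0.41, since fit quality rather than noise level is the available
anchor; `calibrate_noise_sd` reruns that search.

What the generator does *not* emulate: physiological noise structure
(cardiac/respiratory), carry-over effects between blocks, spatial
correlation between vertices, scanner drift beyond what the detrend
operator is tested with, and attentional modulation. Passing recovery and
cross-validation tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
every violation real data can present.

The motion simulator superimposes controllable spikes on smooth
low-amplitude sinusoidal drift so censoring behaviour is exactly
predictable. The vertex-population simulator draws eccentricities
uniformly on [0, 20]° and applies linear parameter gradients (ratios
clipped into (0, 1]), with per-vertex noise.

## Problem sizes used in the automated checks

Structural checks run at the full protocol (360 × 21 per run, 7200 × 41
per measurement set). The stochastic recovery study uses 100 simulated
measurement sets at the calibrated noise; the cross-validated model
comparison averages 3 measurement sets (10 folds each); the bootstrap
coverage study uses 400 outer replicates of 200-iteration bootstraps.
`scripts/acceptance.py` uses 20 measurement sets for recovery and 2 for
cross-validation — sizes chosen to give stable medians while keeping a
single-CPU rerun to about a minute.

## Known limitations

- The ellipse/nonlinearity normalization is one convention among
  observationally equivalent ones; parameter values are comparable only
  under the same convention.
- The informed HRF basis is a stand-in shape family; results depending on
  fine kernel shape should load an empirically derived basis.
- No 3-D (LMS) ellipsoidal generalization and no temporal-frequency
  dependence; stimuli are assumed S-cone silent.
- With an intercept-ones baseline column, a nonzero resting offset in the
  forward model produces a start-of-run hemodynamic transient that the
  GLM cannot represent exactly; the GLM-superset property is exact for
  zero offset.
- OLS assumes exchangeable noise; no AR prewhitening is applied (by
  design, to match the benchmark).
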