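# qcmfit

Quadratic color model (QCM) fitting for chromatic BOLD fMRI block designs.

`qcmfit` is for visual neuroscientists who measure cortical responses to
temporal chromatic modulations in the L/M cone-contrast plane and want a
compact, generalizable model of those responses. It implements the full
analysis chain around the QCM: stimulus and block-design representation,
GLM benchmarking, subject-level HRF estimation, post-minimal-preprocessing
operators, cross-validation and bootstrap machinery, an eccentricity
analysis, and a synthetic-data generator so the entire pipeline is
testable without any MRI data.

## The model

A stimulus is a bipolar modulation summarized by its positive arm: a
chromatic direction θ (degrees counterclockwise from the +L axis) and a
vector-length contrast ‖c‖ with c = (ΔL/L, ΔM/M). The QCM predicts the
BOLD response in three stages:

1. **Equivalent contrast.** A normalized elliptical isoresponse contour —
   major axis (direction of least sensitivity) at angle φ with unit
   length, minor axis ratio r ∈ (0, 1] — defines a quadratic form
   Q = Rᵀ diag(1, 1/r²) R, and the equivalent contrast of a stimulus is
   e(c) = √(cᵀQc). All stimuli on one contour share one equivalent
   contrast; 1/r is the sensitivity ratio between the most and least
   sensitive directions.
2. **Response nonlinearity.** A four-parameter Naka–Rushton function maps
   equivalent contrast to the underlying neural response:
   R(e) = R₀ + A·eⁿ/(eⁿ + σⁿ).
3. **Hemodynamics.** The per-TR neural signal is convolved with a
   subject-specific HRF (a 3-component informed basis with jointly
   estimated weights) to predict the BOLD time course.

The six free parameters (φ, r, A, σ, n, R₀) are estimated by bounded RMSE
minimization against the measured time course, with multistarts over the
ellipse angle. The benchmark is a conventional GLM with one beta per
direction/contrast condition plus a baseline (41 parameters for a full
measurement set of 2 sessions × 10 runs), compared by leave-runs-out
cross-validated R² and 200-iteration run-resampling bootstrap CIs.

## Worked example

Simulate one measurement set from the default ground truth (ellipse angle
45°, minor axis ratio 0.2, noise calibrated to a per-run GLM R² ≈ 0.4) and
fit both models:

```python
import numpy as np
from qcmfit import (
    canonical_hrf, default_sessions, simulate_measurement_set,
    NoiseSpec, DEFAULT_TRUTH, fit_qcm, fit_glm, build_design_matrix,
    concatenate_designs, equivalent_contrast, ChromaticStimulus,
)

hrf = canonical_hrf(tr_s=0.8)
sessions = default_sessions(seed=42)
runs = [run for session in sessions for run in session.runs]
data = simulate_measurement_set(DEFAULT_TRUTH, sessions, hrf,
                                NoiseSpec(sd=1.8), seed=42)
series = np.concatenate([y for session in data for _, y in session])

qcm = fit_qcm(series, runs, hrf, seed=0)
print(f"QCM: angle = {qcm.params.ellipse.angle_deg:.1f} deg, "
      f"minor axis ratio = {qcm.params.ellipse.minor_axis_ratio:.3f}, "
      f"R^2 = {qcm.r2:.3f} ({qcm.n_free_params} free parameters)")

design = concatenate_designs([build_design_matrix(r, hrf) for r in runs])
glm = fit_glm(series, design)
print(f"GLM: R^2 = {glm.r2:.3f} ({glm.n_free_params} free parameters)")

e = equivalent_contrast(ChromaticStimulus(-45.0, 0.12), qcm.params.ellipse)
print(f"equivalent contrast of the 12% L-M stimulus: {e:.2f}")
```

Output:

```
QCM: angle = 45.5 deg, minor axis ratio = 0.196, R^2 = 0.398 (6 free parameters)
GLM: R^2 = 0.401 (41 free parameters)
equivalent contrast of the 12% L-M stimulus: 0.61
```

The QCM recovers the generating ellipse (the cortex-like regime: least
sensitive near L+M at 45°, about five times more sensitive to L−M) and
explains essentially the same variance as the 41-parameter GLM with six
parameters. The 12%-contrast L−M stimulus maps to an equivalent contrast
of ≈ 0.6 — the same effective drive as a 60% L+M stimulus.

A command-line interface covers the same workflows
(`qcmfit simulate | fit-qcm | fit-glm | crossval | bootstrap |
eccentricity`); every command takes `--seed` and writes a provenance
manifest.

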