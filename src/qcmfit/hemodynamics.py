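"""Hemodynamic response kernels, convolution, and subject-level HRF estimation.

The BOLD signal is modeled as the causal convolution of a per-TR neural
signal with a hemodynamic response function (HRF).  Subject-specific HRFs
are expressed in a 3-component basis — the canonical double-gamma shape
plus its temporal and dispersion derivatives, orthogonalized — whose
weights are estimated jointly with the GLM betas by alternating least
squares.  A loader hook accepts externally supplied basis shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

DEFAULT_HRF_DURATION_S = 32.0

# Canonical double-gamma parameters (seconds): response peak, undershoot
# peak, shared dispersion, undershoot ratio.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_DISPERSION = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class HRFKernel:
    """HRF sampled at the scan TR; first sample is lag 0 (causal)."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("HRF kernel must be finite")
        object.__setattr__(self, "values", v)

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.tr_s

    def normalized(self) -> "HRFKernel":
        """Unit-peak normalization (max |value| = 1)."""
        peak = np.max(np.abs(self.values))
        if peak == 0:
            raise ValueError("cannot normalize an all-zero kernel")
        return HRFKernel(values=self.values / peak, tr_s=self.tr_s)

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.tr_s


@dataclass(frozen=True)
class HRFBasis:
    """Exactly three orthonormal kernel components and their weights."""

    components: np.ndarray  # 3 x n_lags
    tr_s: float
    weights: np.ndarray = None

    def __post_init__(self):
        comp = np.asarray(self.components, float)
        if comp.shape[0] != 3:
            raise ValueError("HRF basis must have exactly 3 components")
        object.__setattr__(self, "components", comp)
        w = self.weights
        w = np.array([1.0, 0.0, 0.0]) if w is None else np.asarray(w, float)
        if w.shape != (3,):
            raise ValueError("weights must be a 3-vector")
        object.__setattr__(self, "weights", w)

    def to_kernel(self, weights=None, normalize: bool = True) -> HRFKernel:
        w = self.weights if weights is None else np.asarray(weights, float)
        kernel = HRFKernel(values=w @ self.components, tr_s=self.tr_s)
        return kernel.normalized() if normalize else kernel


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale
        - shape * math.log(scale) - gammaln(shape)
    )
    return out


def double_gamma(t, dispersion: float = _DISPERSION) -> np.ndarray:
    """Canonical double-gamma HRF shape evaluated at lags ``t`` (seconds)."""
    main = _gamma_pdf(t, _PEAK_DELAY / dispersion, dispersion)
    undershoot = _gamma_pdf(t, _UNDERSHOOT_DELAY / dispersion, dispersion)
    return main - _UNDERSHOOT_RATIO * undershoot


def sample_canonical_components(t) -> np.ndarray:
    """Raw (unorthogonalized, unnormalized) basis shapes at lags ``t``:
    double-gamma, temporal derivative, dispersion derivative.  Derivatives
    are central finite differences in onset shift and dispersion, so values
    at a given lag are independent of the sampling grid.
    """
    t = np.asarray(t, float)
    dt, dd = 0.1, 0.01
    canonical = double_gamma(t)
    temporal = (double_gamma(t + dt) - double_gamma(t - dt)) / (2 * dt)
    dispersion = (
        double_gamma(t, _DISPERSION + dd) - double_gamma(t, _DISPERSION - dd)
    ) / (2 * dd)
    return np.vstack([canonical, temporal, dispersion])


def canonical_basis(tr_s: float, duration_s: float = DEFAULT_HRF_DURATION_S) -> HRFBasis:
    """Three-component informed HRF basis sampled at TR.

    Components are Gram-Schmidt orthogonalized in order (canonical first,
    so it is preserved up to scale) and unit-norm.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if duration_s < 10:
        raise ValueError("HRF duration must be at least 10 s")
    t = np.arange(0.0, duration_s, tr_s)
    raw = sample_canonical_components(t)
    comps = []
    for row in raw:
        v = row.copy()
        for u in comps:
            v -= (v @ u) * u
        comps.append(v / np.linalg.norm(v))
    return HRFBasis(components=np.vstack(comps), tr_s=tr_s)


def canonical_hrf(tr_s: float, duration_s: float = DEFAULT_HRF_DURATION_S) -> HRFKernel:
    """Unit-peak canonical double-gamma kernel sampled at TR."""
    t = np.arange(0.0, duration_s, tr_s)
    return HRFKernel(values=double_gamma(t), tr_s=tr_s).normalized()


def load_basis_tsv(path, tr_s: float) -> HRFBasis:
    """Load externally supplied basis shapes from a TSV with columns
    lag_s, comp1, comp2, comp3; resampling is not attempted — lags must
    match the requested TR grid."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    lags = df["lag_s"].to_numpy()
    if not np.allclose(np.diff(lags), tr_s, atol=1e-6):
        raise ValueError("basis file lag grid does not match TR")
    comps = df[[c for c in df.columns if c != "lag_s"]].to_numpy().T
    return HRFBasis(components=comps, tr_s=tr_s)


def convolve_neural(neural: np.ndarray, hrf: HRFKernel, tr_s: float | None = None) -> np.ndarray:
    """Causal discrete convolution of a per-TR neural signal with the HRF,
    truncated to the input length.  Apply per run, before concatenation."""
    if tr_s is not None and not math.isclose(tr_s, hrf.tr_s, abs_tol=1e-9):
        raise ValueError(f"HRF TR {hrf.tr_s} does not match signal TR {tr_s}")
    neural = np.asarray(neural, float)
    return np.convolve(neural, hrf.values)[: len(neural)]


def estimate_subject_hrf(
    timeseries,
    designs,
    duration_s: float = DEFAULT_HRF_DURATION_S,
    tol: float = 1e-8,
    max_iter: int = 100,
    basis: HRFBasis | None = None,
):
    """Jointly estimate a subject HRF and GLM betas from one or more runs.

    Alternating least squares: with the current kernel, the betas are the
    OLS solution for the convolved design; with the betas fixed, the
    3 basis weights minimize the RMSE, which is again a linear problem
    because convolution is linear in the kernel.  The scale ambiguity
    between kernel and betas is resolved by unit-peak normalization of the
    returned kernel.  Deterministic (no randomness involved).

    Parameters
    ----------
    timeseries:
        Concatenated BOLD series matching ``designs``.
    designs:
        List of RunDesign describing each run.

    Returns
    -------
    (HRFBasis with fitted weights, betas) — betas correspond to the
    concatenated design built with the fitted, unit-peak kernel.
    """
    from .stimulus_design import build_design_matrix, concatenate_designs, block_boxcar, BASELINE_LABEL

    y = np.asarray(timeseries, float)
    designs = list(designs)
    tr = designs[0].tr_s
    if basis is None:
        basis = canonical_basis(tr, duration_s)

    # Precompute per-condition boxcars convolved with each basis component,
    # concatenated across runs with shared condition columns.
    labels = []
    for run in designs:
        for lab in run.condition_labels():
            if lab not in labels:
                labels.append(lab)
    n_rows = sum(r.n_timepoints for r in designs)
    # conv_by_comp[i] has one column per condition label
    conv_by_comp = [np.zeros((n_rows, len(labels))) for _ in range(3)]
    row = 0
    for run in designs:
        n = run.n_timepoints
        box = {lab: np.zeros(n) for lab in run.condition_labels()}
        for b in run.stimulus_blocks:
            box[b.stimulus.label] += block_boxcar(run, b)
        for lab, col in box.items():
            j = labels.index(lab)
            for i in range(3):
                conv_by_comp[i][row:row + n, j] = np.convolve(
                    col, basis.components[i]
                )[:n]
        row += n
    ones = np.ones(n_rows)

    def design_for(w):
        X = sum(w[i] * conv_by_comp[i] for i in range(3))
        return np.column_stack([X, ones])

    w = np.array([1.0, 0.0, 0.0])
    X = design_for(w)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design; cannot estimate HRF")
    prev_rmse = np.inf
    betas = None
    for _ in range(max_iter):
        X = design_for(w)
        betas, *_ = np.linalg.lstsq(X, y, rcond=None)
        # weight step: residual after baseline, regressed on the three
        # beta-mixed component columns
        target = y - betas[-1] * ones
        M = np.column_stack([C @ betas[:-1] for C in conv_by_comp])
        w, *_ = np.linalg.lstsq(M, target, rcond=None)
        rmse = float(np.sqrt(np.mean((y - design_for(w) @ betas) ** 2)))
        if abs(prev_rmse - rmse) < tol:
            break
        prev_rmse = rmse
    # normalize: fold kernel scale into the betas
    kernel = HRFBasis(basis.components, tr, w).to_kernel(normalize=False)
    peak = np.max(np.abs(kernel.values))
    w_norm = w / peak
    fitted = HRFBasis(components=basis.components, tr_s=tr, weights=w_norm)
    final_design = concatenate_designs(
        [build_design_matrix(r, fitted.to_kernel(normalize=False)) for r in designs]
    )
    betas, *_ = np.linalg.lstsq(final_design.values, y, rcond=None)
    return fitted, betas
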