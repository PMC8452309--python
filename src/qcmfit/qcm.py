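"""The quadratic color model (QCM).

The QCM predicts the BOLD response to any LM-plane chromatic modulation in
three stages: (1) a normalized elliptical isoresponse contour maps the
stimulus (direction, contrast) to a scalar *equivalent contrast*; (2) a
four-parameter Naka-Rushton function maps equivalent contrast to the
underlying neural response; (3) convolution with a hemodynamic response
function yields the predicted BOLD time course.  Six free parameters in
total: two for the ellipse, four for the nonlinearity.

Conventions.  The ellipse is normalized so its major axis (the direction
of least sensitivity) has unit length; the minor axis ratio r in (0, 1] is
then the relative sensitivity between the least and most sensitive
directions.  Equivalent contrast is e(c) = sqrt(c' Q c) with
Q = R' diag(1, 1/r^2) R, R rotating the major axis onto the first
coordinate.  The Naka-Rushton form is
R(e) = offset + amplitude * e^n / (e^n + sigma^n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .hemodynamics import HRFKernel, convolve_neural
from .stimulus_design import (
    ChromaticStimulus,
    ConeContrastVector,
    RunDesign,
    block_boxcar,
    cone_contrast_from_direction,
)

# Optimizer bounds for the six QCM parameters.
ANGLE_BOUNDS = (0.0, 180.0)
RATIO_BOUNDS = (0.001, 1.0)
AMPLITUDE_BOUNDS = (1e-12, 10.0)
SEMISAT_BOUNDS = (0.001, 5.0)
EXPONENT_BOUNDS = (0.1, 10.0)
OFFSET_BOUNDS = (-5.0, 5.0)

#: Multistart initial angles (degrees); the RMSE surface is 180-degree
#: periodic in angle, so starts tile [0, 180).
MULTISTART_ANGLES = tuple(np.arange(8) * 22.5)


def canonicalize_angle(angle_deg: float) -> float:
    """Ellipse orientation canonicalized to [0, 180) (180-degree symmetry)."""
    return float(angle_deg % 180.0)


@dataclass(frozen=True)
class EllipseParams:
    """Normalized isoresponse ellipse.

    angle_deg: orientation of the major axis (least-sensitive direction),
    degrees counterclockwise from the +L axis, canonical in [0, 180).
    minor_axis_ratio: minor/major axis length ratio in (0, 1].
    """

    angle_deg: float
    minor_axis_ratio: float

    def __post_init__(self):
        if not (0 < self.minor_axis_ratio <= 1):
            raise ValueError(
                f"minor_axis_ratio must be in (0, 1], got {self.minor_axis_ratio}"
            )
        object.__setattr__(self, "angle_deg", canonicalize_angle(self.angle_deg))


@dataclass(frozen=True)
class NakaRushtonParams:
    amplitude: float
    semi_saturation: float
    exponent: float
    offset: float = 0.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.semi_saturation <= 0:
            raise ValueError("semi_saturation must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


@dataclass(frozen=True)
class QCMParams:
    ellipse: EllipseParams
    nr: NakaRushtonParams

    N_FREE_PARAMS = 6

    def as_vector(self) -> np.ndarray:
        return np.array([
            self.ellipse.angle_deg,
            self.ellipse.minor_axis_ratio,
            self.nr.amplitude,
            self.nr.semi_saturation,
            self.nr.exponent,
            self.nr.offset,
        ])

    @staticmethod
    def from_vector(v) -> "QCMParams":
        angle, ratio, amp, sigma, n, offset = v
        return QCMParams(
            ellipse=EllipseParams(angle_deg=angle, minor_axis_ratio=ratio),
            nr=NakaRushtonParams(
                amplitude=amp, semi_saturation=sigma, exponent=n, offset=offset
            ),
        )


@dataclass(frozen=True)
class QuadraticForm:
    """Symmetric positive-definite 2x2 matrix on (L, M) contrast vectors."""

    Q: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q, float)
        if Q.shape != (2, 2) or not np.allclose(Q, Q.T):
            raise ValueError("Q must be a symmetric 2x2 matrix")
        object.__setattr__(self, "Q", Q)


@dataclass
class FitResult:
    """Outcome of a QCM (or constrained-variant) fit."""

    params: QCMParams | None
    r2: float
    rmse: float
    predicted: np.ndarray | None
    n_free_params: int
    degenerate: bool = False
    angle_undefined: bool = False
    diagnostics: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "r2": float(self.r2),
            "rmse": float(self.rmse),
            "n_free_params": int(self.n_free_params),
            "degenerate": bool(self.degenerate),
            "angle_undefined": bool(self.angle_undefined),
            "diagnostics": self.diagnostics,
        }
        if self.params is not None:
            d["params"] = {
                "angle_deg": None if self.angle_undefined
                else float(self.params.ellipse.angle_deg),
                "minor_axis_ratio": float(self.params.ellipse.minor_axis_ratio),
                "amplitude": float(self.params.nr.amplitude),
                "semi_saturation": float(self.params.nr.semi_saturation),
                "exponent": float(self.params.nr.exponent),
                "offset": float(self.params.nr.offset),
            }
        return d


# ---------------------------------------------------------------------------
# Forward model


def quadratic_matrix(ellipse: EllipseParams) -> QuadraticForm:
    """Q = R' diag(1, 1/r^2) R with R rotating the major axis onto the
    first coordinate; equivalent contrast is sqrt(c' Q c)."""
    theta = math.radians(ellipse.angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, s], [-s, c]])
    D = np.diag([1.0, 1.0 / ellipse.minor_axis_ratio**2])
    return QuadraticForm(Q=R.T @ D @ R)


def equivalent_contrast(c, ellipse: EllipseParams) -> float:
    """Equivalent contrast of an LM-plane stimulus.

    Accepts a ConeContrastVector (S must be exactly 0), a ChromaticStimulus,
    or a length-2 (L, M) array.  Homogeneous of degree 1 and symmetric
    under c -> -c; equals the vector length along the major axis and
    ||c||/r along the minor axis.
    """
    if isinstance(c, ChromaticStimulus):
        c = cone_contrast_from_direction(c)
    if isinstance(c, ConeContrastVector):
        if c.S != 0:
            raise ValueError("equivalent contrast is defined in the LM plane (S = 0)")
        v = np.array([c.L, c.M])
    else:
        v = np.asarray(c, float)
        if v.shape != (2,):
            raise ValueError("expected a length-2 (L, M) contrast vector")
    Q = quadratic_matrix(ellipse).Q
    return float(np.sqrt(v @ Q @ v))


def _equivalent_contrasts(directions_deg, contrasts, ellipse_angle, ratio):
    """Vectorized equivalent contrast for arrays of stimuli (internal)."""
    th = np.radians(np.asarray(directions_deg, float))
    u = np.stack([np.cos(th), np.sin(th)], axis=-1)
    phi = math.radians(ellipse_angle)
    c, s = math.cos(phi), math.sin(phi)
    major = u[..., 0] * c + u[..., 1] * s
    minor = -u[..., 0] * s + u[..., 1] * c
    unit_e = np.sqrt(major**2 + (minor / ratio) ** 2)
    return np.asarray(contrasts, float) * unit_e


def naka_rushton(e, nr: NakaRushtonParams):
    """R(e) = offset + amplitude * e^n / (e^n + sigma^n); monotone in e."""
    e_arr = np.asarray(e, float)
    if np.any(e_arr < 0):
        raise ValueError("equivalent contrast must be nonnegative")
    en = e_arr**nr.exponent
    out = nr.offset + nr.amplitude * en / (en + nr.semi_saturation**nr.exponent)
    return float(out) if np.isscalar(e) or e_arr.ndim == 0 else out


def qcm_neural_timecourse(run: RunDesign, params: QCMParams) -> np.ndarray:
    """Piecewise-constant per-TR neural signal: R(e(stimulus)) during
    stimulus blocks, R(0) (= offset) during background blocks."""
    n = run.n_timepoints
    out = np.full(n, naka_rushton(0.0, params.nr))
    for b in run.stimulus_blocks:
        e = equivalent_contrast(b.stimulus, params.ellipse)
        box = block_boxcar(run, b).astype(bool)
        out[box] = naka_rushton(e, params.nr)
    return out


def qcm_predict_bold(run, params: QCMParams, hrf: HRFKernel) -> np.ndarray:
    """Predicted BOLD series: the neural time course convolved with the
    HRF, truncated to run length.  For a list of runs, each run is
    convolved independently and the results concatenated."""
    if isinstance(run, (list, tuple)):
        return np.concatenate([qcm_predict_bold(r, params, hrf) for r in run])
    if not math.isclose(hrf.tr_s, run.tr_s, abs_tol=1e-9):
        raise ValueError(f"HRF TR {hrf.tr_s} does not match run TR {run.tr_s}")
    neural = qcm_neural_timecourse(run, params)
    return convolve_neural(neural, hrf)


def qcm_crf(params: QCMParams, direction_deg: float, contrasts) -> np.ndarray:
    """Baseline-subtracted contrast response function along one direction:
    R(e(direction, c)) - R(0), zero at zero contrast."""
    e = _equivalent_contrasts(
        np.full(len(contrasts), direction_deg),
        contrasts,
        params.ellipse.angle_deg,
        params.ellipse.minor_axis_ratio,
    )
    return naka_rushton(e, params.nr) - naka_rushton(0.0, params.nr)


def isoresponse_contour(params: EllipseParams, n_points: int = 100) -> np.ndarray:
    """(L, M) points with equivalent contrast exactly 1: the normalized
    ellipse with major semi-axis 1 and minor semi-axis r."""
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    phi = math.radians(params.angle_deg)
    c, s = math.cos(phi), math.sin(phi)
    # ellipse-frame coordinates, rotated back into the LM plane
    major = np.cos(t)
    minor = params.minor_axis_ratio * np.sin(t)
    L = c * major - s * minor
    M = s * major + c * minor
    return np.column_stack([L, M])


# ---------------------------------------------------------------------------
# Fitting


class _CompiledDesign:
    """Precomputed linear pieces of the forward model for fast fitting.

    Block boxcars tile each run, so the predicted BOLD series is linear in
    the per-condition neural responses: pred = C_stim @ R(e) + c_bg * R(0),
    where the columns are per-condition boxcars convolved with the HRF.
    """

    def __init__(self, designs, hrf: HRFKernel):
        designs = list(designs)
        for run in designs:
            if not math.isclose(hrf.tr_s, run.tr_s, abs_tol=1e-9):
                raise ValueError("HRF TR does not match run TR")
        labels = []
        stim_of = {}
        for run in designs:
            for b in run.stimulus_blocks:
                if b.stimulus.label not in stim_of:
                    stim_of[b.stimulus.label] = b.stimulus
                    labels.append(b.stimulus.label)
        n_rows = sum(r.n_timepoints for r in designs)
        C = np.zeros((n_rows, len(labels)))
        bg = np.zeros(n_rows)
        row = 0
        for run in designs:
            n = run.n_timepoints
            box = {lab: np.zeros(n) for lab in labels}
            bgbox = np.zeros(n)
            for b in run.blocks:
                if b.is_background:
                    bgbox += block_boxcar(run, b)
                else:
                    box[b.stimulus.label] += block_boxcar(run, b)
            for j, lab in enumerate(labels):
                C[row:row + n, j] = np.convolve(box[lab], hrf.values)[:n]
            bg[row:row + n] = np.convolve(bgbox, hrf.values)[:n]
            row += n
        self.C = C
        self.bg = bg
        self.labels = labels
        self.directions = np.array(
            [stim_of[lab].direction_deg for lab in labels]
        )
        self.contrasts = np.array([stim_of[lab].contrast for lab in labels])

    def predict(self, theta) -> np.ndarray:
        angle, ratio, amp, sigma, n, offset = theta
        e = _equivalent_contrasts(self.directions, self.contrasts, angle, ratio)
        en = e**n
        resp = offset + amp * en / (en + sigma**n)
        return self.C @ resp + self.bg * offset


def _rmse(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(measured, predicted) -> float:
    """Coefficient of determination about the mean of the measured series."""
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    ss_res = np.sum((measured - predicted) ** 2)
    ss_tot = np.sum((measured - np.mean(measured)) ** 2)
    if ss_tot == 0:
        return float("nan")  # constant series: R^2 undefined
    return float(1.0 - ss_res / ss_tot)


def _fit(
    timeseries,
    designs,
    hrf,
    locked_angle_deg=None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    y = np.asarray(timeseries, float)
    if isinstance(designs, RunDesign):
        designs = [designs]
    compiled = _CompiledDesign(designs, hrf)
    n_rows = compiled.C.shape[0]
    if len(y) != n_rows:
        raise ValueError(
            f"timeseries length {len(y)} does not match designs ({n_rows} TRs)"
        )
    n_free = 5 if locked_angle_deg is not None else 6
    if np.ptp(y) == 0:
        return FitResult(
            params=None, r2=0.0, rmse=0.0, predicted=None,
            n_free_params=n_free, degenerate=True,
            diagnostics={"reason": "all-constant time series"},
        )

    scale = max(float(np.std(y)), 1e-6)
    amp0 = min(max(4.0 * scale, 0.1), AMPLITUDE_BOUNDS[1])
    rng = np.random.default_rng(seed)

    if locked_angle_deg is not None:
        locked = canonicalize_angle(locked_angle_deg)

        def objective(x):
            ratio, amp, sigma, n, offset = x
            return _rmse(y, compiled.predict((locked, ratio, amp, sigma, n, offset)))

        bounds = [RATIO_BOUNDS, AMPLITUDE_BOUNDS, SEMISAT_BOUNDS,
                  EXPONENT_BOUNDS, OFFSET_BOUNDS]
        starts = [
            np.array([r0, amp0, s0, 1.5, 0.0])
            for r0 in (0.2, 0.5, 0.9)
            for s0 in (0.2, 0.8)
        ]
    else:

        def objective(x):
            return _rmse(y, compiled.predict(x))

        bounds = [ANGLE_BOUNDS, RATIO_BOUNDS, AMPLITUDE_BOUNDS,
                  SEMISAT_BOUNDS, EXPONENT_BOUNDS, OFFSET_BOUNDS]
        starts = [
            np.array([a0, 0.3, amp0, 0.5, 1.5, 0.0])
            for a0 in MULTISTART_ANGLES[:n_starts]
        ]
        # one jittered extra start guards against a shared bad basin
        starts.append(np.array([
            rng.uniform(0, 180), rng.uniform(0.05, 1.0), amp0,
            rng.uniform(0.1, 1.0), rng.uniform(0.5, 3.0), 0.0,
        ]))

    best = None
    n_converged = 0
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    if locked_angle_deg is not None:
        theta = np.concatenate([[locked], best.x])
    else:
        theta = best.x.copy()
        theta[0] = canonicalize_angle(theta[0])
    predicted = compiled.predict(theta)
    params = QCMParams.from_vector(theta)
    # ratio == 1 makes the contour a circle: the angle is unidentifiable
    angle_undefined = locked_angle_deg is None and params.ellipse.minor_axis_ratio >= 1.0 - 1e-6
    return FitResult(
        params=params,
        r2=r_squared(y, predicted),
        rmse=float(best.fun),
        predicted=predicted,
        n_free_params=n_free,
        angle_undefined=angle_undefined,
        diagnostics={
            "n_starts": len(starts),
            "n_converged": int(n_converged),
            "seed": seed,
        },
    )


def fit_qcm(timeseries, designs, hrf: HRFKernel, n_starts: int = 8, seed: int = 0) -> FitResult:
    """Fit the six QCM parameters to a (possibly concatenated) BOLD series
    by bounded RMSE minimization with seeded multistarts over angle."""
    return _fit(timeseries, designs, hrf, n_starts=n_starts, seed=seed)


def fit_qcm_locked(timeseries, designs, hrf: HRFKernel, locked_angle_deg: float,
                   seed: int = 0) -> FitResult:
    """QCM fit with the ellipse angle held fixed (5 free parameters)."""
    return _fit(timeseries, designs, hrf, locked_angle_deg=locked_angle_deg, seed=seed)
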