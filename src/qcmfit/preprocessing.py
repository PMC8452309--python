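"""Time-series operators applied after minimal preprocessing.

Fixed pipeline order: percent signal change -> nuisance regression ->
motion censoring -> polynomial detrend -> ROI median.  Censoring is mask
propagation (censored TRs are excluded from downstream losses), never
interpolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import HRFKernel, convolve_neural

#: Radius of the sphere used to convert rotations to arc length (mm).
ROTATION_SPHERE_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5
CENSOR_WINDOW_TR = 3

PIPELINE_ORDER = ("psc", "nuisance", "censor", "detrend", "median")


@dataclass(frozen=True)
class MotionParams:
    """Per-TR rigid-body motion: translations x, y, z (mm) and rotations
    yaw, pitch, roll (radians by default)."""

    values: np.ndarray  # n_tr x 6
    relative: bool = True  # frame-to-frame differences vs absolute
    rotation_unit: str = "rad"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError(f"motion table must have 6 columns, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("motion parameters must be finite")
        if self.rotation_unit not in ("rad", "deg"):
            raise ValueError("rotation_unit must be 'rad' or 'deg'")
        if self.rotation_unit == "deg":
            v = v.copy()
            v[:, 3:] = np.radians(v[:, 3:])
            object.__setattr__(self, "rotation_unit", "rad")
        object.__setattr__(self, "values", v)

    def as_relative(self) -> "MotionParams":
        """Frame-to-frame differences; first frame is zero motion."""
        if self.relative:
            return self
        rel = np.diff(self.values, axis=0, prepend=self.values[:1])
        return MotionParams(values=rel, relative=True)


@dataclass(frozen=True)
class CensorMask:
    """Per-TR keep (True) / drop (False) flags."""

    keep: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "keep", np.asarray(self.keep, bool))

    @property
    def n_censored(self) -> int:
        return int(np.sum(~self.keep))

    def __len__(self):
        return len(self.keep)


def percent_signal_change(raw: np.ndarray) -> np.ndarray:
    """100 * (x - mean) / mean per voxel (columns for 2-D input)."""
    x = np.asarray(raw, float)
    mean = x.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("zero-mean voxel: percent signal change undefined")
    return 100.0 * (x - mean) / mean


def framewise_displacement(motion: MotionParams) -> np.ndarray:
    """Per-TR framewise displacement in mm.

    Relative rotations are converted to the arc length they subtend on a
    50 mm sphere; FD is the L2 norm of the resulting 6-vector of
    millimeter displacements.  The first frame has FD 0 by construction
    of the relative estimates.
    """
    rel = motion.as_relative().values.copy()
    rel[:, 3:] *= ROTATION_SPHERE_RADIUS_MM
    return np.linalg.norm(rel, axis=1)


def censor_mask(
    fd: np.ndarray,
    threshold: float = FD_THRESHOLD_MM,
    window: int = CENSOR_WINDOW_TR,
) -> CensorMask:
    """Drop ``window`` contiguous TRs centered on every FD exceedance,
    clipped at run edges; overlapping windows merge."""
    if window % 2 != 1:
        raise ValueError("censor window must be odd (centered)")
    fd = np.asarray(fd, float)
    keep = np.ones(len(fd), bool)
    half = window // 2
    for t in np.flatnonzero(fd > threshold):
        keep[max(0, t - half): t + half + 1] = False
    return CensorMask(keep=keep)


def nuisance_regress(
    ts: np.ndarray,
    motion: MotionParams,
    attention_onsets_tr,
    hrf: HRFKernel,
) -> np.ndarray:
    """OLS residual of the series against motion and attention regressors.

    Motion columns are mean-centered and scaled by their standard
    deviations (constant columns are zero-filled with a warning); the
    attention regressor is a delta train at the event TRs convolved with
    the HRF.  An intercept is included so the residual is mean-free.
    """
    y = np.asarray(ts, float)
    n = y.shape[0]
    mot = motion.values
    if mot.shape[0] != n:
        raise ValueError("motion table length does not match series")
    cols = []
    for j in range(6):
        col = mot[:, j] - mot[:, j].mean()
        sd = col.std()
        if sd == 0:
            warnings.warn(f"constant motion column {j}; zero-filled")
            cols.append(np.zeros(n))
        else:
            cols.append(col / sd)
    deltas = np.zeros(n)
    for t in attention_onsets_tr:
        deltas[int(t)] = 1.0
    cols.append(convolve_neural(deltas, hrf))
    X = np.column_stack([np.ones(n)] + cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def polynomial_detrend(ts: np.ndarray, order: int = 5, keep=None) -> np.ndarray:
    """Remove a least-squares polynomial of the given order per voxel.

    ``keep`` (boolean mask) restricts the fit to uncensored timepoints;
    the polynomial is evaluated and subtracted at all timepoints.
    """
    y = np.asarray(ts, float)
    n = y.shape[0]
    if n <= order + 1:
        raise ValueError(f"series length {n} too short for order-{order} detrend")
    t = np.linspace(-1, 1, n)  # scaled for conditioning
    V = np.vander(t, order + 1)
    if keep is None:
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    else:
        keep = np.asarray(keep, bool)
        coef, *_ = np.linalg.lstsq(V[keep], y[keep], rcond=None)
    return y - V @ coef


def roi_median(ts_matrix: np.ndarray) -> np.ndarray:
    """Median across voxels at each TR.  Input is TRs x voxels."""
    x = np.asarray(ts_matrix, float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("ROI matrix must be TRs x voxels with >= 1 voxel")
    return np.median(x, axis=1)


def preprocess_run(
    raw: np.ndarray,
    motion: MotionParams | None = None,
    attention_onsets_tr=(),
    hrf: HRFKernel | None = None,
    detrend_order: int = 5,
    fd_threshold: float = FD_THRESHOLD_MM,
) -> tuple:
    """Full fixed-order pipeline for one run: PSC -> nuisance -> censor ->
    detrend -> ROI median.  Returns (median series, CensorMask).

    ``raw`` is TRs x voxels (a 1-D series is treated as a single voxel).
    """
    x = np.asarray(raw, float)
    if x.ndim == 1:
        x = x[:, None]
    x = percent_signal_change(x)
    if motion is not None:
        if hrf is None:
            raise ValueError("nuisance regression requires an HRF for attention events")
        x = nuisance_regress(x, motion, attention_onsets_tr, hrf)
        mask = censor_mask(framewise_displacement(motion), threshold=fd_threshold)
    else:
        mask = CensorMask(keep=np.ones(x.shape[0], bool))
    x = polynomial_detrend(x, order=detrend_order, keep=mask.keep)
    return roi_median(x), mask
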