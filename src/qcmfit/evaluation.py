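"""Model evaluation: cross-validation, bootstrap CIs, residual
diagnostics, and the eccentricity robust-regression analysis.

A *measurement-set dataset* is a pair of sessions, each a list of
``(RunDesign, series)`` tuples (10 runs per session in the full
protocol).  Model fit procedures are callables
``fit(designs, series) -> predict`` where ``predict(designs)`` returns a
concatenated predicted series for arbitrary runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .glm import fit_glm
from .hemodynamics import HRFKernel
from .qcm import (
    ChromaticStimulus,
    QCMParams,
    equivalent_contrast,
    fit_qcm,
    fit_qcm_locked,
    naka_rushton,
    qcm_crf,
    qcm_predict_bold,
    r_squared,
)
from .stimulus_design import build_design_matrix, concatenate_designs

BOOTSTRAP_ITERATIONS = 200
CI_LEVEL = 68.0
#: Residual averaging window after block onset, TR indices [lo, hi).
RESIDUAL_WINDOW_TR = (4, 14)
#: Tukey bisquare tuning constant for the robust eccentricity fit.
BISQUARE_C = 4.685


@dataclass(frozen=True)
class CVResult:
    mean_r2: dict          # model name -> mean cross-validated R^2
    per_fold_r2: dict      # model name -> list of per-fold R^2
    folds: tuple           # (session1 run index, session2 run index) pairs


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    low: float
    high: float
    n_iterations: int
    level: float = CI_LEVEL
    out_of_interval: bool = False  # percentile interval excluded the estimate

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class EccentricityFit:
    """Robust line through per-vertex parameter values vs eccentricity."""

    slope: float
    offset: float
    weights: np.ndarray

    @property
    def delta_0_20(self) -> float:
        """Magnitude of the parameter change from 0 to 20 deg eccentricity."""
        return abs(self.slope) * 20.0


# --- model fit procedures ---------------------------------------------------


def qcm_model(hrf: HRFKernel, **fit_kwargs):
    """Fit procedure for the full QCM."""

    def fit(designs, series):
        result = fit_qcm(series, designs, hrf, **fit_kwargs)
        if result.degenerate:
            raise RuntimeError("degenerate QCM fit")

        def predict(test_designs):
            return qcm_predict_bold(list(test_designs), result.params, hrf)

        predict.fit_result = result
        return predict

    return fit


def qcm_locked_model(hrf: HRFKernel, locked_angle_deg: float = 0.0, **fit_kwargs):
    """Fit procedure for the angle-locked QCM."""

    def fit(designs, series):
        result = fit_qcm_locked(series, designs, hrf, locked_angle_deg, **fit_kwargs)

        def predict(test_designs):
            return qcm_predict_bold(list(test_designs), result.params, hrf)

        predict.fit_result = result
        return predict

    return fit


def glm_model(hrf: HRFKernel):
    """Fit procedure for the benchmark GLM; held-out prediction applies the
    training betas to the held-out runs' design columns (matched by label)."""

    def fit(designs, series):
        design = concatenate_designs([build_design_matrix(r, hrf) for r in designs])
        glm = fit_glm(series, design)
        beta_of = dict(zip(glm.labels, glm.betas))

        def predict(test_designs):
            X = concatenate_designs(
                [build_design_matrix(r, hrf) for r in test_designs]
            )
            missing = [lab for lab in X.column_labels if lab not in beta_of]
            if missing:
                raise ValueError(f"untrained conditions in test runs: {missing}")
            b = np.array([beta_of[lab] for lab in X.column_labels])
            return X.values @ b

        predict.fit_result = glm
        return predict

    return fit


# --- cross-validation -------------------------------------------------------


def leave_runs_out_cv(models: dict, data, seed: int = 0) -> CVResult:
    """Leave-runs-out cross-validation over a measurement-set dataset.

    Runs from session 1 and session 2 are randomly paired (a seeded
    one-to-one pairing); each of the 10 folds holds out one pair, fits
    every model to the remaining 18 runs, and scores R^2 between the
    held-out series and its prediction.  A model that fails on a fold is
    recorded and that fold skipped for it, with a warning.
    """
    session1, session2 = data
    if len(session1) != len(session2):
        raise ValueError("sessions must contain equally many runs")
    n = len(session1)
    rng = np.random.default_rng(seed)
    pairing = rng.permutation(n)
    folds = tuple((k, int(pairing[k])) for k in range(n))

    per_fold = {name: [] for name in models}
    failures = {name: [] for name in models}
    for k, (i1, i2) in enumerate(folds):
        train = [r for j, r in enumerate(session1) if j != i1]
        train += [r for j, r in enumerate(session2) if j != i2]
        test = [session1[i1], session2[i2]]
        train_designs = [d for d, _ in train]
        train_series = np.concatenate([s for _, s in train])
        test_designs = [d for d, _ in test]
        test_series = np.concatenate([s for _, s in test])
        for name, model in models.items():
            try:
                predict = model(train_designs, train_series)
                per_fold[name].append(
                    r_squared(test_series, predict(test_designs))
                )
            except Exception as err:  # noqa: BLE001 - fold-level robustness
                warnings.warn(f"model {name!r} failed on fold {k}: {err}")
                failures[name].append(k)
    mean_r2 = {
        name: float(np.mean(vals)) if vals else float("nan")
        for name, vals in per_fold.items()
    }
    return CVResult(mean_r2=mean_r2, per_fold_r2=per_fold, folds=folds)


def leave_session_out_cv(data, hrf: HRFKernel, seed: int = 0) -> dict:
    """Fit the QCM to each session separately and predict CRFs for the
    held-out session's directions; GLM betas from the full dataset serve
    as the comparison.

    Returns a dict with, per held-out session index, the predicted CRF
    responses keyed ``(direction_deg, contrast)``, plus the per-session
    QCM fits and the full-data GLM CRFs.
    """
    from .glm import betas_to_crfs

    session1, session2 = data
    dirs1 = {d.stimulus.direction_deg for ds, _ in session1
             for d in ds.stimulus_blocks}
    dirs2 = {d.stimulus.direction_deg for ds, _ in session2
             for d in ds.stimulus_blocks}
    if dirs1 & dirs2:
        raise ValueError("sessions must contain disjoint direction sets")

    all_runs = list(session1) + list(session2)
    full_design = concatenate_designs(
        [build_design_matrix(d, hrf) for d, _ in all_runs]
    )
    full_series = np.concatenate([s for _, s in all_runs])
    glm = fit_glm(full_series, full_design)
    glm_crfs = betas_to_crfs(glm)

    out = {"glm_crfs": glm_crfs, "fits": {}, "predicted": {}}
    sessions = (session1, session2)
    for fit_idx, held_idx in ((0, 1), (1, 0)):
        fit_runs = sessions[fit_idx]
        held_runs = sessions[held_idx]
        result = fit_qcm(
            np.concatenate([s for _, s in fit_runs]),
            [d for d, _ in fit_runs],
            hrf,
            seed=seed,
        )
        out["fits"][fit_idx] = result
        preds = {}
        held_conditions = sorted({
            (b.stimulus.direction_deg, b.stimulus.contrast)
            for ds, _ in held_runs
            for b in ds.stimulus_blocks
        })
        by_dir: dict = {}
        for d, c in held_conditions:
            by_dir.setdefault(d, []).append(c)
        for d, cs in by_dir.items():
            cs = sorted(cs)
            responses = qcm_crf(result.params, d, cs)
            for c, r in zip(cs, responses):
                preds[(d, c)] = float(r)
        out["predicted"][held_idx] = preds
    return out


# --- bootstrap --------------------------------------------------------------


def bootstrap_ci(
    fit_fn,
    runs,
    n_iter: int = BOOTSTRAP_ITERATIONS,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI for a scalar statistic of a run collection.

    ``runs`` is a list of sessions (each a list of run items, in whatever
    form ``fit_fn`` expects); resampling draws runs with replacement
    within each session independently, preserving the session structure.
    """
    if sum(len(s) for s in runs) < 2:
        raise ValueError("bootstrap requires at least 2 runs")
    rng = np.random.default_rng(seed)
    estimate = float(fit_fn(runs))
    samples = np.empty(n_iter)
    for i in range(n_iter):
        resampled = [
            [session[j] for j in rng.integers(0, len(session), len(session))]
            for session in runs
        ]
        try:
            samples[i] = fit_fn(resampled)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"bootstrap iteration {i} failed: {err}") from err
    lo, hi = np.percentile(samples, [50 - level / 2, 50 + level / 2])
    return BootstrapCI(
        estimate=estimate,
        low=float(lo),
        high=float(hi),
        n_iterations=n_iter,
        level=level,
        out_of_interval=not (lo <= estimate <= hi),
    )


# --- residual diagnostics ---------------------------------------------------


def residual_by_direction(
    predicted,
    measured,
    designs,
    window_tr: tuple = RESIDUAL_WINDOW_TR,
    keep=None,
) -> dict:
    """Mean residual per chromatic direction, collapsed over contrast.

    For every stimulus block, residuals (measured - predicted) are
    averaged over TR indices ``[onset + lo, onset + hi)`` relative to
    block onset (clipped at run end, censored TRs excluded), then averaged
    across all blocks sharing a direction.
    """
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    residual = measured - predicted
    keep = np.ones(len(residual), bool) if keep is None else np.asarray(keep, bool)
    lo, hi = window_tr
    by_dir: dict = {}
    offset = 0
    for run in designs:
        n = run.n_timepoints
        for b in run.stimulus_blocks:
            onset_tr = int(round(b.onset_s / run.tr_s))
            a = offset + min(onset_tr + lo, n)
            z = offset + min(onset_tr + hi, n)
            window_keep = keep[a:z]
            if window_keep.any():
                val = float(residual[a:z][window_keep].mean())
                by_dir.setdefault(b.stimulus.direction_deg, []).append(val)
        offset += n
    return {d: float(np.mean(v)) for d, v in sorted(by_dir.items())}


# --- eccentricity analysis --------------------------------------------------


def robust_fit(x, y, weights=None) -> EccentricityFit:
    """Robust (IRLS, Tukey bisquare c=4.685) line through parameter values
    vs eccentricity.  Optional per-point ``weights`` (e.g. vertex R^2)
    rescale the observations before the robust fit; off by default.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("robust fit requires at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all eccentricities identical; slope undefined")
    X = sm.add_constant(x)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, float))
        X = X * w[:, None]
        y = y * w
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    res = model.fit()
    return EccentricityFit(
        slope=float(res.params[1]),
        offset=float(res.params[0]),
        weights=np.asarray(res.weights),
    )


def predict_response_at_stimulus(per_vertex_params, stimulus: ChromaticStimulus) -> np.ndarray:
    """Per-vertex predicted neural response to one stimulus, using each
    vertex's own parameters: R(e(stimulus)).  Vertices with an undefined
    (unidentifiable) angle are skipped and reported as NaN.
    """
    out = np.full(len(per_vertex_params), np.nan)
    for i, p in enumerate(per_vertex_params):
        if p is None:
            continue
        e = equivalent_contrast(stimulus, p.ellipse)
        out[i] = naka_rushton(e, p.nr)
    return out
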