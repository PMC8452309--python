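"""Benchmark GLM and the constrained Naka-Rushton CRF model family.

The GLM fits one beta per direction/contrast condition plus a baseline
(41 free parameters on a full measurement set) by ordinary least squares.
Grouping betas by chromatic direction yields contrast response functions
(CRFs).  The Naka-Rushton family replaces the per-condition betas with a
monotone Naka-Rushton CRF per direction, with a configurable subset of
parameters shared across directions (the offset is always shared).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hemodynamics import HRFKernel
from .qcm import (
    AMPLITUDE_BOUNDS,
    EXPONENT_BOUNDS,
    OFFSET_BOUNDS,
    SEMISAT_BOUNDS,
    FitResult,
    _CompiledDesign,
    _rmse,
    r_squared,
)
from .stimulus_design import BASELINE_LABEL, DesignMatrix, parse_condition_label

LOCKABLE = ("amplitude", "exponent")


@dataclass(frozen=True)
class GLMResult:
    betas: np.ndarray
    labels: tuple
    predicted: np.ndarray
    r2: float
    rank: int
    condition_number: float

    @property
    def n_free_params(self) -> int:
        return len(self.betas)

    @property
    def baseline_beta(self) -> float:
        return float(self.betas[self.labels.index(BASELINE_LABEL)])


@dataclass(frozen=True)
class CRF:
    """Baseline-subtracted contrast response function for one direction."""

    direction_deg: float
    contrasts: tuple
    responses: tuple
    ci_low: tuple | None = None
    ci_high: tuple | None = None

    def __post_init__(self):
        c = tuple(float(x) for x in self.contrasts)
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("contrasts must be strictly increasing")
        object.__setattr__(self, "contrasts", c)
        object.__setattr__(self, "responses", tuple(float(x) for x in self.responses))


@dataclass(frozen=True)
class NRFamilySpec:
    """Parameter-sharing scheme for the Naka-Rushton CRF family.

    ``locked_params`` names the parameters (from amplitude, exponent)
    shared across directions; semi-saturation is always free per direction
    and the offset is always shared.
    """

    locked_params: frozenset = frozenset()

    def __post_init__(self):
        locked = frozenset(self.locked_params)
        unknown = locked - set(LOCKABLE)
        if unknown:
            raise ValueError(
                f"cannot lock {sorted(unknown)}; lockable: {LOCKABLE} "
                "(offset is always shared, semi-saturation always free)"
            )
        object.__setattr__(self, "locked_params", locked)

    def n_free_params(self, n_directions: int) -> int:
        per_dir = 1 + sum(1 for p in LOCKABLE if p not in self.locked_params)
        shared = 1 + len(self.locked_params)  # offset + locked params
        return n_directions * per_dir + shared


def fit_glm(timeseries, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares on the stimulus design matrix.

    Uses an SVD-backed solver, so a rank-deficient design yields the
    minimum-norm solution (reported with a warning and the condition
    number).
    """
    y = np.asarray(timeseries, float)
    X = design.values
    if X.shape[0] != len(y):
        raise ValueError(
            f"design rows ({X.shape[0]}) do not match series length ({len(y)})"
        )
    betas, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {X.shape[1]}, "
            f"condition number {cond:.3g}); minimum-norm solution returned"
        )
    predicted = X @ betas
    return GLMResult(
        betas=betas,
        labels=tuple(design.column_labels),
        predicted=predicted,
        r2=r_squared(y, predicted),
        rank=int(rank),
        condition_number=cond,
    )


def betas_to_crfs(glm: GLMResult, labels=None) -> list:
    """Group condition betas by chromatic direction into CRFs, with the
    baseline beta subtracted (zero response at zero contrast)."""
    labels = glm.labels if labels is None else tuple(labels)
    baseline = glm.baseline_beta
    by_direction: dict = {}
    for lab, beta in zip(glm.labels, glm.betas):
        if lab == BASELINE_LABEL:
            continue
        if lab not in labels:
            raise ValueError(f"condition label {lab!r} missing from label set")
        direction, contrast = parse_condition_label(lab)
        by_direction.setdefault(direction, []).append((contrast, float(beta) - baseline))
    crfs = []
    for direction in sorted(by_direction):
        pts = sorted(by_direction[direction])
        crfs.append(CRF(
            direction_deg=direction,
            contrasts=tuple(c for c, _ in pts),
            responses=tuple(r for _, r in pts),
        ))
    return crfs


def _pack_spec(spec: NRFamilySpec, directions):
    """Index layout for the family parameter vector:
    [offset, shared locked..., then per-direction free blocks]."""
    shared = ["offset"] + sorted(spec.locked_params)
    free_per_dir = ["semi_saturation"] + [p for p in LOCKABLE if p not in spec.locked_params]
    return shared, free_per_dir


def _family_responses(x, spec, directions, cond_dirs, cond_contrasts):
    shared, free_per_dir = _pack_spec(spec, directions)
    vals = {name: x[i] for i, name in enumerate(shared)}
    off = len(shared)
    per_dir = {}
    for d in directions:
        block = {name: x[off + i] for i, name in enumerate(free_per_dir)}
        off += len(free_per_dir)
        per_dir[d] = block
    resp = np.empty(len(cond_dirs))
    for j, (d, c) in enumerate(zip(cond_dirs, cond_contrasts)):
        p = per_dir[d]
        amp = p.get("amplitude", vals.get("amplitude"))
        n = p.get("exponent", vals.get("exponent"))
        sigma = p["semi_saturation"]
        cn = c**n
        resp[j] = vals["offset"] + amp * cn / (cn + sigma**n)
    return resp


def fit_nr_crf_family(
    timeseries,
    designs,
    hrf: HRFKernel,
    spec: NRFamilySpec,
    on: str = "timecourse",
    seed: int = 0,
) -> FitResult:
    """Fit the constrained Naka-Rushton CRF family.

    The forward prediction replaces per-condition betas with per-direction
    Naka-Rushton responses of stimulus contrast; fitted CRFs are monotone
    nondecreasing in contrast by construction (amplitude > 0).  Fit by
    bounded RMSE minimization on the time course (``on="timecourse"``); or,
    with ``on="betas"``, directly on baseline-subtracted GLM beta weights.
    """
    y = np.asarray(timeseries, float)
    compiled = _CompiledDesign(list(designs), hrf)
    directions = sorted(set(compiled.directions.tolist()))
    shared, free_per_dir = _pack_spec(spec, directions)
    n_free = spec.n_free_params(len(directions))

    bounds_of = {
        "offset": OFFSET_BOUNDS,
        "amplitude": AMPLITUDE_BOUNDS,
        "exponent": EXPONENT_BOUNDS,
        "semi_saturation": (0.001, 2.0),
    }
    init_of = {"offset": 0.0, "amplitude": max(4.0 * float(np.std(y)), 0.1),
               "exponent": 1.5}
    bounds = [bounds_of[name] for name in shared]
    x0 = [init_of.get(name, 0.0) for name in shared]
    for d in directions:
        for name in free_per_dir:
            bounds.append(bounds_of[name])
            if name == "semi_saturation":
                # per-direction scale: half the maximum contrast tested
                cmax = compiled.contrasts[compiled.directions == d].max()
                x0.append(0.5 * cmax)
            else:
                x0.append(init_of[name])
    x0 = np.asarray(x0, float)

    if on == "timecourse":

        def objective(x):
            resp = _family_responses(
                x, spec, directions, compiled.directions, compiled.contrasts
            )
            pred = compiled.C @ resp + compiled.bg * x[0]
            return _rmse(y, pred)

    elif on == "betas":
        from .stimulus_design import concatenate_designs, build_design_matrix

        design = concatenate_designs(
            [build_design_matrix(r, hrf) for r in designs]
        )
        glm = fit_glm(y, design)
        target = np.array([
            glm.betas[glm.labels.index(lab)] - glm.baseline_beta
            for lab in compiled.labels
        ])

        def objective(x):
            resp = _family_responses(
                x, spec, directions, compiled.directions, compiled.contrasts
            )
            return _rmse(target, resp - x[0])

    else:
        raise ValueError("on must be 'timecourse' or 'betas'")

    best = None
    for scale in (1.0, 0.3):
        start = x0.copy()
        start[len(shared):] *= scale if free_per_dir != ["semi_saturation"] else 1.0
        res = minimize(objective, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res

    resp = _family_responses(
        best.x, spec, directions, compiled.directions, compiled.contrasts
    )
    predicted = compiled.C @ resp + compiled.bg * best.x[0]
    r2 = r_squared(y, predicted) if on == "timecourse" else float("nan")
    return FitResult(
        params=None,
        r2=r2,
        rmse=float(best.fun),
        predicted=predicted if on == "timecourse" else None,
        n_free_params=n_free,
        diagnostics={
            "family_params": best.x.tolist(),
            "shared": shared,
            "free_per_direction": free_per_dir,
            "directions": directions,
            "fit_space": on,
        },
    )


def family_crfs(fit: FitResult, contrasts_by_direction: dict) -> list:
    """Evaluate a fitted family as baseline-subtracted CRFs."""
    spec = NRFamilySpec(frozenset(
        p for p in LOCKABLE if p in fit.diagnostics["shared"]
    ))
    directions = fit.diagnostics["directions"]
    x = np.asarray(fit.diagnostics["family_params"])
    crfs = []
    for d in directions:
        cs = sorted(contrasts_by_direction[d])
        resp = _family_responses(
            x, spec, directions, np.full(len(cs), d), np.asarray(cs)
        )
        crfs.append(CRF(
            direction_deg=d,
            contrasts=tuple(cs),
            responses=tuple(resp - x[0]),
        ))
    return crfs
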