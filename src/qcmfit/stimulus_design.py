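"""Chromatic stimulus representation and block-design construction.

Stimuli are bipolar temporal modulations in the LM cone-contrast plane,
summarized by the positive arm: a chromatic direction (degrees
counterclockwise from the +L axis) and a vector-length contrast.  The
experiment presents 8 directions x 5 log-spaced contrasts in 12-s blocks,
24 blocks per 288-s run, TR = 0.8 s, 10 runs per session, two sessions per
measurement set with disjoint direction groups, and two measurement sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hemodynamics import HRFKernel

# Protocol constants: the block-design geometry of the experiment.
TR_S = 0.8
BLOCK_DURATION_S = 12.0
RUN_DURATION_S = 288.0
BLOCKS_PER_RUN = 24
STIM_BLOCKS_PER_RUN = 20
BACKGROUND_BLOCKS_PER_RUN = 4
RUNS_PER_SESSION = 10
N_MEASUREMENT_SETS = 2

#: Default relative contrast ladder (fractions of the per-direction maximum).
RELATIVE_LEVELS = (1.0, 0.5, 0.25, 0.125, 0.0625)

#: Direction groups per session, degrees in the LM plane.
SESSION1_DIRECTIONS = (-45.0, 0.0, 45.0, 90.0)
SESSION2_DIRECTIONS = (-22.5, 22.5, 67.5, 112.5)

#: Maximum vector-length contrast per chromatic direction (device gamut).
MAX_CONTRAST = {
    -45.0: 0.12,
    -22.5: 0.085,
    0.0: 0.14,
    22.5: 0.20,
    45.0: 0.60,
    67.5: 0.40,
    90.0: 0.22,
    112.5: 0.13,
}

BASELINE_LABEL = "baseline"


def canonicalize_direction(direction_deg: float) -> float:
    """Map an angle to the canonical interval [-180, 180)."""
    return float((direction_deg + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class ChromaticStimulus:
    """Positive arm of a bipolar LM-plane modulation.

    Parameters
    ----------
    direction_deg:
        Chromatic direction, degrees counterclockwise from the +L axis.
        Canonicalized to [-180, 180).
    contrast:
        Vector length (L2 norm) of the positive-arm cone-contrast vector,
        as a dimensionless fraction (0.12 = 12%).
    """

    direction_deg: float
    contrast: float

    def __post_init__(self):
        if self.contrast < 0:
            raise ValueError(f"contrast must be >= 0, got {self.contrast}")
        object.__setattr__(
            self, "direction_deg", canonicalize_direction(self.direction_deg)
        )

    @property
    def label(self) -> str:
        return condition_label(self.direction_deg, self.contrast)


@dataclass(frozen=True)
class ConeContrastVector:
    """Signed contrast on each cone class.  S is zero for all LM-plane stimuli."""

    L: float
    M: float
    S: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S])


@dataclass(frozen=True)
class ContrastLadder:
    max_contrast: float
    relative_levels: tuple = RELATIVE_LEVELS

    def __post_init__(self):
        if not (0 < self.max_contrast <= 1):
            raise ValueError(
                f"max_contrast must be in (0, 1], got {self.max_contrast}"
            )
        levels = tuple(float(v) for v in self.relative_levels)
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError("relative_levels must be strictly decreasing")
        object.__setattr__(self, "relative_levels", levels)

    @property
    def levels(self) -> tuple:
        """Absolute contrast levels, largest first."""
        return tuple(self.max_contrast * r for r in self.relative_levels)


@dataclass(frozen=True)
class Block:
    """One block of the design; ``stimulus=None`` marks a background block."""

    onset_s: float
    duration_s: float = BLOCK_DURATION_S
    stimulus: ChromaticStimulus | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def is_background(self) -> bool:
        return self.stimulus is None


@dataclass(frozen=True)
class RunDesign:
    blocks: tuple
    tr_s: float = TR_S

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))

    @property
    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    @property
    def n_timepoints(self) -> int:
        n = self.duration_s / self.tr_s
        return int(round(n))

    @property
    def stimulus_blocks(self) -> tuple:
        return tuple(b for b in self.blocks if not b.is_background)

    def condition_labels(self) -> list:
        """Unique stimulus condition labels, in first-appearance order."""
        seen = []
        for b in self.stimulus_blocks:
            if b.stimulus.label not in seen:
                seen.append(b.stimulus.label)
        return seen


@dataclass(frozen=True)
class SessionDesign:
    directions: tuple
    runs: tuple  # of RunDesign


@dataclass(frozen=True)
class ExperimentDesign:
    """Two measurement sets x two sessions x 10 runs."""

    measurement_sets: tuple  # of (SessionDesign, SessionDesign)

    @property
    def n_blocks(self) -> int:
        return sum(
            len(run.blocks)
            for mset in self.measurement_sets
            for session in mset
            for run in session.runs
        )

    def all_conditions(self) -> list:
        labels = []
        for mset in self.measurement_sets:
            for session in mset:
                for run in session.runs:
                    for lab in run.condition_labels():
                        if lab not in labels:
                            labels.append(lab)
        return labels


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray  # timepoints x regressors
    column_labels: tuple
    tr_s: float
    run_slices: tuple = ()  # row slices per run after concatenation

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("one label required per regressor column")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def condition_label(direction_deg: float, contrast: float) -> str:
    return f"dir{canonicalize_direction(direction_deg):g}_con{contrast:.6g}"


def parse_condition_label(label: str) -> tuple:
    """Inverse of :func:`condition_label`; returns (direction_deg, contrast)."""
    if not label.startswith("dir") or "_con" not in label:
        raise ValueError(f"not a condition label: {label!r}")
    head, tail = label[3:].split("_con")
    return float(head), float(tail)


# ---------------------------------------------------------------------------
# Operations


def cone_contrast_from_direction(stimulus: ChromaticStimulus) -> ConeContrastVector:
    """Cone-contrast coordinates of the positive arm.

    L = contrast*cos(direction), M = contrast*sin(direction), S = 0; the
    L2 norm of (L, M) equals the stimulus contrast.
    """
    theta = math.radians(stimulus.direction_deg)
    return ConeContrastVector(
        L=stimulus.contrast * math.cos(theta),
        M=stimulus.contrast * math.sin(theta),
        S=0.0,
    )


def stimulus_from_cone_contrast(c: ConeContrastVector) -> ChromaticStimulus:
    """Round-trip inverse of :func:`cone_contrast_from_direction`."""
    if c.S != 0:
        raise ValueError("stimulus must lie in the LM plane (S = 0)")
    return ChromaticStimulus(
        direction_deg=math.degrees(math.atan2(c.M, c.L)),
        contrast=math.hypot(c.L, c.M),
    )


def build_contrast_ladder(max_contrast: float) -> ContrastLadder:
    """Log-spaced (factor-of-two) ladder below the per-direction maximum."""
    return ContrastLadder(max_contrast=max_contrast)


def generate_run_design(
    directions,
    ladders,
    seed,
    tr_s: float = TR_S,
    block_duration_s: float = BLOCK_DURATION_S,
    n_background: int = BACKGROUND_BLOCKS_PER_RUN,
) -> RunDesign:
    """One pseudorandomized run: each direction/contrast pair once, plus
    background blocks, in a seeded uniform shuffle.

    Parameters
    ----------
    directions:
        The session's chromatic directions (4 in the full protocol).
    ladders:
        Mapping direction -> ContrastLadder, or a single ladder applied to
        every direction.
    seed:
        Seeds the block-order shuffle; same seed, same order.
    """
    directions = [canonicalize_direction(d) for d in directions]
    if len(set(directions)) != len(directions):
        raise ValueError("duplicate directions in run design")
    if isinstance(ladders, ContrastLadder):
        ladders = {d: ladders for d in directions}
    else:
        ladders = {canonicalize_direction(d): l for d, l in ladders.items()}

    stimuli = [
        ChromaticStimulus(d, level)
        for d in directions
        for level in ladders[d].levels
    ]
    slots: list = stimuli + [None] * n_background
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    blocks = []
    t = 0.0
    for idx in order:
        blocks.append(Block(onset_s=t, duration_s=block_duration_s, stimulus=slots[idx]))
        t += block_duration_s
    return RunDesign(blocks=tuple(blocks), tr_s=tr_s)


def default_ladders(directions) -> dict:
    return {
        canonicalize_direction(d): build_contrast_ladder(
            MAX_CONTRAST[canonicalize_direction(d)]
        )
        for d in directions
    }


def default_experiment(seed: int = 0) -> ExperimentDesign:
    """The full protocol: 2 measurement sets x 2 sessions x 10 runs, with
    the standard direction grouping and per-direction maximum contrasts.
    Run orders are re-randomized across runs and measurement sets from the
    single top-level seed.
    """
    ss = np.random.SeedSequence(seed)
    msets = []
    for _ in range(N_MEASUREMENT_SETS):
        sessions = []
        for dirs in (SESSION1_DIRECTIONS, SESSION2_DIRECTIONS):
            ladders = default_ladders(dirs)
            runs = tuple(
                generate_run_design(dirs, ladders, seed=child)
                for child in ss.spawn(RUNS_PER_SESSION)
            )
            sessions.append(SessionDesign(directions=tuple(dirs), runs=runs))
        msets.append(tuple(sessions))
    return ExperimentDesign(measurement_sets=tuple(msets))


def block_boxcar(run: RunDesign, block: Block) -> np.ndarray:
    """Binary per-TR indicator for one block, length = run timepoints."""
    n = run.n_timepoints
    out = np.zeros(n)
    lo = int(round(block.onset_s / run.tr_s))
    hi = int(round((block.onset_s + block.duration_s) / run.tr_s))
    out[lo:min(hi, n)] = 1.0
    return out


def build_design_matrix(run: RunDesign, hrf: HRFKernel) -> DesignMatrix:
    """GLM design matrix for one run.

    One column per unique direction/contrast condition — the binary block
    indicator convolved with the HRF, truncated to run length — plus a
    single baseline column of ones (the background blocks carry no
    regressor of their own and are absorbed by the baseline).
    """
    if not math.isclose(hrf.tr_s, run.tr_s, rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"HRF sampled at TR {hrf.tr_s} does not match run TR {run.tr_s}"
        )
    for b in run.blocks:
        if not math.isclose(b.duration_s / run.tr_s,
                            round(b.duration_s / run.tr_s), abs_tol=1e-6):
            raise ValueError("run TR must divide block durations evenly")
    n = run.n_timepoints
    labels = run.condition_labels()
    cols = {lab: np.zeros(n) for lab in labels}
    for b in run.stimulus_blocks:
        cols[b.stimulus.label] += block_boxcar(run, b)
    values = np.column_stack(
        [np.convolve(cols[lab], hrf.values)[:n] for lab in labels]
        + [np.ones(n)]
    )
    return DesignMatrix(
        values=values,
        column_labels=tuple(labels) + (BASELINE_LABEL,),
        tr_s=run.tr_s,
        run_slices=(slice(0, n),),
    )


def concatenate_designs(designs) -> DesignMatrix:
    """Stack run design matrices; identical condition labels share a column
    and all runs share the single baseline column.  Per-run blocks stay
    block-diagonal: convolution never bleeds across run boundaries because
    each run was convolved independently.
    """
    designs = list(designs)
    if len(designs) == 1:
        return designs[0]
    tr = designs[0].tr_s
    if any(not math.isclose(d.tr_s, tr, abs_tol=1e-9) for d in designs):
        raise ValueError("inconsistent TR across concatenated designs")
    merged = []
    for d in designs:
        for lab in d.column_labels:
            if lab != BASELINE_LABEL and lab not in merged:
                merged.append(lab)
    merged.append(BASELINE_LABEL)
    total_rows = sum(d.values.shape[0] for d in designs)
    out = np.zeros((total_rows, len(merged)))
    col_of = {lab: j for j, lab in enumerate(merged)}
    slices = []
    row = 0
    for d in designs:
        nrow = d.values.shape[0]
        sl = slice(row, row + nrow)
        for j, lab in enumerate(d.column_labels):
            out[sl, col_of[lab]] = d.values[:, j]
        slices.append(sl)
        row += nrow
    return DesignMatrix(
        values=out, column_labels=tuple(merged), tr_s=tr, run_slices=tuple(slices)
    )
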