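"""Configuration, tabular I/O, and run manifests.

Formats: BIDS-style events TSV (onset, duration, direction_deg, contrast,
condition_label), time-series and motion TSV, 2-column HRF TSV
(lag_s, value), YAML/JSON experiment configs, JSON results and manifests.
Onsets are written with 3-decimal (ms) precision and validated against
the TR grid to 1e-6 s.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hemodynamics import HRFKernel
from .stimulus_design import (
    BACKGROUND_BLOCKS_PER_RUN,
    BLOCK_DURATION_S,
    MAX_CONTRAST,
    RELATIVE_LEVELS,
    RUNS_PER_SESSION,
    N_MEASUREMENT_SETS,
    SESSION1_DIRECTIONS,
    SESSION2_DIRECTIONS,
    TR_S,
    Block,
    ChromaticStimulus,
    ContrastLadder,
    ExperimentDesign,
    RunDesign,
    SessionDesign,
    canonicalize_direction,
    generate_run_design,
)

EVENTS_COLUMNS = ("onset", "duration", "direction_deg", "contrast", "condition_label")
BACKGROUND_MARKER = "background"

CONFIG_KEYS = {
    "directions_session1",
    "directions_session2",
    "max_contrasts",
    "relative_levels",
    "tr_s",
    "block_duration_s",
    "runs_per_session",
    "n_background_blocks",
    "measurement_sets",
    "seed",
}


# --- events -----------------------------------------------------------------


def write_events_tsv(run: RunDesign, path) -> None:
    rows = []
    for b in run.blocks:
        if b.is_background:
            rows.append((round(b.onset_s, 3), round(b.duration_s, 3),
                         "", "", BACKGROUND_MARKER))
        else:
            rows.append((
                round(b.onset_s, 3),
                round(b.duration_s, 3),
                b.stimulus.direction_deg,
                b.stimulus.contrast,
                b.stimulus.label,
            ))
    pd.DataFrame(rows, columns=EVENTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, tr_s: float = TR_S) -> RunDesign:
    """Reconstruct a RunDesign from an events table.

    Gaps between listed events are preserved as background blocks;
    overlapping blocks are rejected; onsets must sit on the TR grid to
    within 1e-6 s.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration") if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing required column(s): {missing}")
    has_cond = all(c in df.columns for c in ("direction_deg", "contrast"))
    if not has_cond:
        raise ValueError(
            "events table missing required column(s): ['direction_deg', 'contrast']"
        )
    df = df.sort_values("onset").reset_index(drop=True)
    blocks = []
    cursor = 0.0
    for _, row in df.iterrows():
        onset = float(row["onset"])
        duration = float(row["duration"])
        grid = onset / tr_s
        if abs(grid - round(grid)) * tr_s > 1e-6:
            raise ValueError(f"onset {onset} not aligned to TR grid ({tr_s} s)")
        if onset < cursor - 1e-9:
            raise ValueError(f"overlapping blocks at onset {onset}")
        if onset > cursor + 1e-9:  # gap: background
            blocks.append(Block(onset_s=cursor, duration_s=onset - cursor, stimulus=None))
        is_bg = (
            ("condition_label" in df.columns and row.get("condition_label") == BACKGROUND_MARKER)
            or pd.isna(row["direction_deg"])
            or row["direction_deg"] == ""
        )
        stim = None if is_bg else ChromaticStimulus(
            direction_deg=float(row["direction_deg"]),
            contrast=float(row["contrast"]),
        )
        blocks.append(Block(onset_s=onset, duration_s=duration, stimulus=stim))
        cursor = onset + duration
    return RunDesign(blocks=tuple(blocks), tr_s=tr_s)


# --- tabular series ---------------------------------------------------------


def write_timeseries_tsv(series, path, column_prefix: str = "v") -> None:
    arr = np.atleast_2d(np.asarray(series, float))
    if arr.shape[0] == 1:
        arr = arr.T
    cols = [f"{column_prefix}{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path) -> np.ndarray:
    arr = pd.read_csv(path, sep="\t").to_numpy(float)
    return arr[:, 0] if arr.shape[1] == 1 else arr


def write_motion_tsv(motion, path) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_yaw", "rot_pitch", "rot_roll"]
    pd.DataFrame(motion.values, columns=cols).to_csv(path, sep="\t", index=False)


def read_motion_tsv(path, relative: bool = True, rotation_unit: str = "rad"):
    from .preprocessing import MotionParams

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {df.shape[1]}")
    return MotionParams(values=df.to_numpy(float), relative=relative,
                        rotation_unit=rotation_unit)


def write_hrf_tsv(hrf: HRFKernel, path) -> None:
    pd.DataFrame({"lag_s": hrf.lags_s, "value": hrf.values}).to_csv(
        path, sep="\t", index=False
    )


def read_hrf_tsv(path) -> HRFKernel:
    df = pd.read_csv(path, sep="\t")
    for col in ("lag_s", "value"):
        if col not in df.columns:
            raise ValueError(f"HRF table missing column {col!r}")
    lags = df["lag_s"].to_numpy(float)
    tr = float(lags[1] - lags[0]) if len(lags) > 1 else TR_S
    if len(lags) > 2 and not np.allclose(np.diff(lags), tr, atol=1e-9):
        raise ValueError("HRF lag grid must be uniform")
    return HRFKernel(values=df["value"].to_numpy(float), tr_s=tr)


# --- experiment config ------------------------------------------------------


def load_experiment_config(path=None, overrides: dict | None = None):
    """Load an experiment configuration (YAML or JSON) and build the
    design.  Missing keys fall back to the standard protocol (8
    directions with the shipped per-direction maximum contrasts, TR
    0.8 s, 12 s blocks, 10 runs/session, 2 measurement sets); unknown
    keys are rejected with their paths.

    Returns (ExperimentDesign, resolved config dict).
    """
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        cfg = yaml.safe_load(text) or {}
    if overrides:
        cfg.update(overrides)
    unknown = sorted(set(cfg) - CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")

    dirs1 = tuple(cfg.get("directions_session1", SESSION1_DIRECTIONS))
    dirs2 = tuple(cfg.get("directions_session2", SESSION2_DIRECTIONS))
    relative_levels = tuple(cfg.get("relative_levels", RELATIVE_LEVELS))
    max_contrasts = {
        canonicalize_direction(float(k)): float(v)
        for k, v in cfg.get(
            "max_contrasts",
            {d: MAX_CONTRAST[d] for d in dirs1 + dirs2 if d in MAX_CONTRAST},
        ).items()
    }
    errors = []
    for d, v in max_contrasts.items():
        if not (0 < v <= 1):
            errors.append(f"max_contrasts[{d}]: must be in (0, 1], got {v}")
    for d in dirs1 + dirs2:
        if canonicalize_direction(d) not in max_contrasts:
            errors.append(f"max_contrasts[{d}]: missing")
    tr_s = float(cfg.get("tr_s", TR_S))
    block_s = float(cfg.get("block_duration_s", BLOCK_DURATION_S))
    if tr_s <= 0:
        errors.append(f"tr_s: must be positive, got {tr_s}")
    if errors:
        raise ValueError("invalid experiment config:\n  " + "\n  ".join(errors))

    runs_per_session = int(cfg.get("runs_per_session", RUNS_PER_SESSION))
    n_background = int(cfg.get("n_background_blocks", BACKGROUND_BLOCKS_PER_RUN))
    n_sets = int(cfg.get("measurement_sets", N_MEASUREMENT_SETS))
    seed = int(cfg.get("seed", 0))

    ss = np.random.SeedSequence(seed)
    msets = []
    for _ in range(n_sets):
        sessions = []
        for dirs in (dirs1, dirs2):
            ladders = {
                canonicalize_direction(d): ContrastLadder(
                    max_contrast=max_contrasts[canonicalize_direction(d)],
                    relative_levels=relative_levels,
                )
                for d in dirs
            }
            runs = tuple(
                generate_run_design(
                    dirs, ladders, seed=child, tr_s=tr_s,
                    block_duration_s=block_s, n_background=n_background,
                )
                for child in ss.spawn(runs_per_session)
            )
            sessions.append(SessionDesign(directions=tuple(dirs), runs=runs))
        msets.append(tuple(sessions))
    design = ExperimentDesign(measurement_sets=tuple(msets))
    resolved = {
        "directions_session1": list(dirs1),
        "directions_session2": list(dirs2),
        "max_contrasts": {str(k): v for k, v in max_contrasts.items()},
        "relative_levels": list(relative_levels),
        "tr_s": tr_s,
        "block_duration_s": block_s,
        "runs_per_session": runs_per_session,
        "n_background_blocks": n_background,
        "measurement_sets": n_sets,
        "seed": seed,
    }
    return design, resolved


# --- manifests --------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    seed: int
    inputs: tuple
    version: str
    timestamp: float


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, command: str, config: dict, seed: int, inputs=()) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config),
        seed=seed,
        inputs=tuple(str(p) for p in inputs),
        version=__version__,
        timestamp=time.time(),
    )
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
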