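"""Delimited-text serialization with schema validation.

All tables are tab-separated with a single header row and round-trip
losslessly (floats are written with Python's shortest-repr format).
``validate_io`` gives line-numbered diagnostics for malformed files;
line numbers count from 1 including the header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agents import BehaviorSession
from .tac import TAC, FrameSchedule
from .task import TaskConfig, TaskSchedule

__all__ = [
    "ValidationError",
    "write_schedule",
    "read_schedule",
    "write_session",
    "read_session",
    "write_tac",
    "read_tac",
    "write_voxel_grid",
    "read_voxel_grid",
    "validate_io",
]

SEP = "\t"


class ValidationError(ValueError):
    """A parse/validation failure with a file and line reference."""

    def __init__(self, path: str | Path, line: int | None, message: str) -> None:
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def _write(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=SEP, index=False)


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(path, None, "file does not exist")
    try:
        df = pd.read_csv(path, sep=SEP, float_precision="round_trip")
    except Exception as exc:  # malformed delimiter structure
        raise ValidationError(path, None, f"unparseable table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(path, 1, f"missing columns {missing}")
    return df


def write_schedule(schedule: TaskSchedule, path: str | Path) -> None:
    _write(schedule.to_frame(), path)


def read_schedule(path: str | Path, config: TaskConfig | None = None) -> TaskSchedule:
    df = _read(path, ["trial_index", "best_action", "p_reward_A", "onset_s", "iti_s"])
    cfg = config or TaskConfig()
    for i, row in df.iterrows():
        line = i + 2
        if row["best_action"] not in ("A", "B"):
            raise ValidationError(path, line, f"best_action {row['best_action']!r} not in A/B")
        if not 0.0 <= row["p_reward_A"] <= 1.0:
            raise ValidationError(path, line, f"p_reward_A {row['p_reward_A']} outside [0, 1]")
        if row["iti_s"] < 0:
            raise ValidationError(path, line, "negative ITI")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if not (np.diff(onsets) > 0).all():
        bad = int(np.argmin(np.diff(onsets) > 0))
        raise ValidationError(path, bad + 3, "onsets not strictly increasing")
    best = df["best_action"].to_numpy(dtype="<U1")
    flips = np.flatnonzero(best[1:] != best[:-1]) + 2  # 1-based trial of flip
    return TaskSchedule(
        config=cfg,
        best_action=best,
        p_reward_a=df["p_reward_A"].to_numpy(dtype=float),
        onset_s=onsets,
        iti_s=df["iti_s"].to_numpy(dtype=float),
        reversal_trials=tuple(int(f) for f in flips),
    )


def write_session(session: BehaviorSession, path: str | Path) -> None:
    _write(session.trials, path)


def read_session(path: str | Path, schedule: TaskSchedule | None = None) -> BehaviorSession:
    df = _read(path, ["trial_index", "choice", "outcome"])
    for i, row in df.iterrows():
        line = i + 2
        if row["choice"] not in ("A", "B"):
            raise ValidationError(path, line, f"choice {row['choice']!r} not in A/B")
        if row["outcome"] not in (0, 1):
            raise ValidationError(path, line, f"outcome {row['outcome']!r} not binary")
        if row["trial_index"] != i + 1:
            raise ValidationError(path, line, f"trial_index {row['trial_index']} not contiguous")
    df["trial_index"] = df["trial_index"].astype(int)
    df["outcome"] = df["outcome"].astype(int)
    return BehaviorSession(trials=df, schedule=schedule)


def write_tac(tac: TAC, path: str | Path) -> None:
    _write(tac.to_frame(), path)


def read_tac(path: str | Path) -> TAC:
    df = _read(path, ["frame_start_s", "frame_end_s", "activity"])
    start = df["frame_start_s"].to_numpy(dtype=float)
    end = df["frame_end_s"].to_numpy(dtype=float)
    act = df["activity"].to_numpy(dtype=float)
    for i in range(len(df)):
        line = i + 2
        if end[i] <= start[i]:
            raise ValidationError(path, line, f"frame end {end[i]} <= start {start[i]}")
        if i > 0 and not np.isclose(start[i], end[i - 1]):
            raise ValidationError(path, line, "frames not contiguous")
        if act[i] < 0:
            raise ValidationError(path, line, f"negative activity {act[i]}")
    return TAC(FrameSchedule(start, end), act)


def write_voxel_grid(grid: np.ndarray, frame_schedule: FrameSchedule, path: str | Path) -> None:
    """Flat (i, j, k, frame_0...frame_{n-1}) table for a 4-D TAC grid."""
    grid = np.asarray(grid, dtype=float)
    idx = np.array(list(np.ndindex(grid.shape[:3])))
    cols = {"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2]}
    flat = grid.reshape(-1, grid.shape[3])
    for f in range(grid.shape[3]):
        cols[f"frame_{f}"] = flat[:, f]
    _write(pd.DataFrame(cols), path)


def read_voxel_grid(path: str | Path, frame_schedule: FrameSchedule) -> np.ndarray:
    n_frames = frame_schedule.n_frames
    df = _read(path, ["i", "j", "k"] + [f"frame_{f}" for f in range(n_frames)])
    shape = tuple(int(df[c].max()) + 1 for c in ("i", "j", "k"))
    grid = np.full(shape + (n_frames,), np.nan)
    frames = df[[f"frame_{f}" for f in range(n_frames)]].to_numpy(dtype=float)
    grid[df["i"].astype(int), df["j"].astype(int), df["k"].astype(int)] = frames
    if np.isnan(grid).any():
        raise ValidationError(path, None, "voxel table does not cover the full grid")
    return grid


_READERS = {
    "schedule": read_schedule,
    "session": read_session,
    "tac": read_tac,
}


def validate_io(path: str | Path, kind: str):
    """Schema-checked parse of a delimited file.

    ``kind`` is one of 'schedule', 'session' or 'tac'. Raises
    :class:`ValidationError` with a line reference on malformed input.
    """
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_READERS)}") from None
    return reader(path)
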