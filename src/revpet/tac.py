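"""PET frame schedules, time-activity curves and gamma-variate responses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FrameSchedule", "TAC", "GammaResponse"]

# (count, duration_s) blocks of the default 68-min dynamic acquisition
DEFAULT_FRAME_BLOCKS = ((6, 10.0), (6, 20.0), (6, 40.0), (9, 60.0), (26, 120.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, strictly increasing PET frame timing in seconds."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise ValueError("frame start/end arrays must be matching 1-D arrays")
        if not (end > start).all():
            raise ValueError("every frame must have end_s > start_s")
        if not np.allclose(start[1:], end[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def default_68min(cls) -> "FrameSchedule":
        """The standard 53-frame dynamic schedule:
        6x10 s, 6x20 s, 6x40 s, 9x60 s, 26x120 s (4080 s total)."""
        durations = np.concatenate([np.full(n, d) for n, d in DEFAULT_FRAME_BLOCKS])
        end = np.cumsum(durations)
        return cls(start_s=end - durations, end_s=end)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])


@dataclass(frozen=True)
class TAC:
    """Decay-corrected activity per frame (arbitrary units, >= 0)."""

    frame_schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", activity)
        if activity.shape != (self.frame_schedule.n_frames,):
            raise ValueError("activity length must equal the frame count")
        if not np.isfinite(activity).all():
            raise ValueError("activity must be finite")
        if (activity < 0).any():
            raise ValueError("activity must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_s": self.frame_schedule.start_s,
                "frame_end_s": self.frame_schedule.end_s,
                "activity": self.activity,
            }
        )


@dataclass(frozen=True)
class GammaResponse:
    """Unit-peak gamma-variate response curve.

    value(t) = u^a * exp(a * (1 - u)) with u = (t - onset)/(peak - onset)
    for t > onset, zero before; a is the sharpness exponent. The maximum
    is exactly 1 at ``peak_s``.
    """

    onset_s: float
    peak_s: float
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_s <= self.onset_s:
            raise ValueError("peak_s must be after onset_s")
        if self.sharpness < 1.0:
            raise ValueError("sharpness exponent must be >= 1")

    def value(self, t_s: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        u = (t - self.onset_s) / (self.peak_s - self.onset_s)
        with np.errstate(invalid="ignore"):
            v = np.where(u > 0, u ** self.sharpness * np.exp(self.sharpness * (1.0 - u)), 0.0)
        return v
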