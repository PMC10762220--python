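"""Probabilistic reversal-learning task schedules.

The task is a two-forced-choice card-guessing game: one of two actions
(coded ``A``/``B``) is rewarded with high probability (default 80%), the
other with the complement. A long stable phase (150 trials with ``A``
best) is followed by a volatile phase in which the best action reverses
every 25 trials, for 250 trials in total. Each trial occupies a fixed
6 s of events (2 s response window, 2 s fixation, 2 s outcome) plus a
jittered inter-trial interval in [1, 13] s, arranged so that every
25-trial block spans exactly 5 minutes of wall time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TaskConfig", "TaskSchedule", "generate_schedule"]


class TaskConfigError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal-learning paradigm.

    Defaults reproduce the standard design: 250 trials, 150 stable
    trials, reversals every 25 trials thereafter, 80/20 contingencies,
    3 currency units per win, and 300 s per 25-trial block.
    """

    n_trials: int = 250
    stable_trials: int = 150
    block_len: int = 25
    p_high: float = 0.8
    reward_value: float = 3.0
    response_window_s: float = 2.0
    fixation_s: float = 2.0
    outcome_s: float = 2.0
    iti_min_s: float = 1.0
    iti_max_s: float = 13.0
    block_duration_s: float = 300.0
    seed: int = 0

    @property
    def event_duration_s(self) -> float:
        """Fixed per-trial duration excluding the ITI."""
        return self.response_window_s + self.fixation_s + self.outcome_s

    def validate(self) -> None:
        if self.n_trials <= 0 or self.stable_trials <= 0 or self.block_len <= 0:
            raise TaskConfigError("trial counts must be positive")
        if self.stable_trials >= self.n_trials:
            raise TaskConfigError("stable_trials must be < n_trials")
        if (self.n_trials - self.stable_trials) % self.block_len != 0:
            raise TaskConfigError(
                "block_len must divide the number of volatile trials "
                f"({self.n_trials - self.stable_trials})"
            )
        if self.stable_trials % self.block_len != 0:
            raise TaskConfigError("block_len must divide stable_trials")
        if not 0.0 < self.p_high < 1.0:
            raise TaskConfigError("p_high must be in (0, 1)")
        if self.iti_min_s < 0 or self.iti_max_s < self.iti_min_s:
            raise TaskConfigError("require 0 <= iti_min_s <= iti_max_s")
        lo = self.block_len * (self.event_duration_s + self.iti_min_s)
        hi = self.block_len * (self.event_duration_s + self.iti_max_s)
        if not lo <= self.block_duration_s <= hi:
            raise TaskConfigError(
                f"block_duration_s={self.block_duration_s} unattainable: "
                f"feasible range is [{lo}, {hi}] given event and ITI bounds"
            )


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial contingencies and timing for one task run.

    ``best_action`` holds 'A' or 'B' per trial; ``p_reward_a`` is the
    reward probability of action A; ``onset_s`` is the trial onset in
    seconds from task start; ``iti_s`` the inter-trial interval that
    follows the trial's outcome screen.
    """

    config: TaskConfig
    best_action: np.ndarray  # array of 'A'/'B', length n_trials
    p_reward_a: np.ndarray
    onset_s: np.ndarray
    iti_s: np.ndarray
    reversal_trials: tuple[int, ...] = field(default=())  # 1-based

    @property
    def n_trials(self) -> int:
        return len(self.best_action)

    @property
    def trial_index(self) -> np.ndarray:
        """1-based trial indices."""
        return np.arange(1, self.n_trials + 1)

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.iti_s) + self.n_trials * self.config.event_duration_s)

    def best_action_before(self, reversal_trial: int) -> str:
        """Best action on the trial preceding a given 1-based reversal trial."""
        if reversal_trial not in self.reversal_trials:
            raise ValueError(f"trial {reversal_trial} is not a reversal trial")
        return str(self.best_action[reversal_trial - 2])

    def p_reward(self, trial_index: int, action: str) -> float:
        """Reward probability of ``action`` on a 1-based trial index."""
        p_a = float(self.p_reward_a[trial_index - 1])
        return p_a if action == "A" else 1.0 - p_a

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": self.trial_index,
                "best_action": self.best_action,
                "p_reward_A": self.p_reward_a,
                "onset_s": self.onset_s,
                "iti_s": self.iti_s,
            }
        )


def _adjust_itis(raw: np.ndarray, target_sum: float, lo: float, hi: float) -> np.ndarray:
    """Shift raw ITIs by a constant to hit ``target_sum``, then clip to
    [lo, hi] and redistribute any residual over non-saturated entries.

    Converges because the per-ITI target mean lies strictly inside the
    bounds for any feasible configuration.
    """
    iti = raw + (target_sum - raw.sum()) / raw.size
    for _ in range(1000):
        iti = np.clip(iti, lo, hi)
        residual = target_sum - iti.sum()
        if abs(residual) < 1e-12:
            break
        if residual > 0:
            free = iti < hi - 1e-15
        else:
            free = iti > lo + 1e-15
        if not free.any():  # pragma: no cover - feasibility checked upstream
            raise TaskConfigError("cannot satisfy block duration within ITI bounds")
        iti[free] += residual / free.sum()
    # force exact block total on one entry with slack
    residual = target_sum - iti.sum()
    if residual != 0.0:
        idx = int(np.argmax(np.minimum(hi - iti, iti - lo)))
        iti[idx] += residual
    return iti


def generate_schedule(config: TaskConfig | None = None) -> TaskSchedule:
    """Generate a deterministic task schedule from a configuration.

    ITIs are drawn uniformly on [iti_min_s, iti_max_s] from a seeded
    generator, then adjusted within bounds so that every consecutive
    ``block_len``-trial block spans exactly ``block_duration_s``.
    """
    config = config or TaskConfig()
    config.validate()
    rng = np.random.default_rng([config.seed, 0x5EED])

    n = config.n_trials
    n_blocks = n // config.block_len
    iti_target = config.block_duration_s - config.block_len * config.event_duration_s
    itis = np.empty(n)
    for b in range(n_blocks):
        raw = rng.uniform(config.iti_min_s, config.iti_max_s, size=config.block_len)
        itis[b * config.block_len : (b + 1) * config.block_len] = _adjust_itis(
            raw, iti_target, config.iti_min_s, config.iti_max_s
        )

    durations = config.event_duration_s + itis
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    best = np.full(n, "A", dtype="<U1")
    reversals = []
    current = "A"
    for t in range(config.stable_trials, n, config.block_len):
        current = "B" if current == "A" else "A"
        reversals.append(t + 1)  # 1-based index of the first flipped trial
        best[t : t + config.block_len] = current

    p_a = np.where(best == "A", config.p_high, 1.0 - config.p_high)
    return TaskSchedule(
        config=config,
        best_action=best,
        p_reward_a=p_a,
        onset_s=onsets,
        iti_s=itis,
        reversal_trials=tuple(reversals),
    )
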