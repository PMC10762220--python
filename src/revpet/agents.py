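"""Softmax Q-learning agents played against a task schedule.

Agents keep one expected value per action, choose by a softmax over the
two values (inverse temperature β) and update the chosen action's value
by the delta rule with learning rate α after each outcome. Choice and
outcome randomness use independent seeded streams, so the outcome draws
are comparable across agents playing the same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import q_update, softmax_prob
from .task import TaskSchedule

__all__ = ["AgentSpec", "BehaviorSession", "simulate_agent", "simulate_fixed_policy"]

ACTIONS = ("A", "B")


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth parameters of a simulated Q-learning agent."""

    alpha: float
    beta: float
    q_init: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


@dataclass
class BehaviorSession:
    """Choices and outcomes of one agent or participant on a schedule."""

    trials: pd.DataFrame  # columns: trial_index, choice, outcome[, rt_s]
    schedule: TaskSchedule | None = None
    agent: AgentSpec | None = None

    def __post_init__(self) -> None:
        required = {"trial_index", "choice", "outcome"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"session table missing columns: {sorted(missing)}")
        idx = self.trials["trial_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError("trial_index must be contiguous from 1")
        out = self.trials["outcome"].to_numpy()
        if not np.isin(out, [0, 1]).all():
            raise ValueError("outcomes must be binary {0, 1}")
        if not self.trials["choice"].isin(ACTIONS).all():
            raise ValueError("choices must be 'A' or 'B'")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        return self.trials["choice"].to_numpy()

    @property
    def outcomes(self) -> np.ndarray:
        return self.trials["outcome"].to_numpy(dtype=float)


def simulate_agent(schedule: TaskSchedule, agent: AgentSpec) -> BehaviorSession:
    """Forward-simulate a softmax Q-learning agent on a schedule.

    The choice stream is seeded from ``agent.seed`` and the outcome
    stream from ``schedule.config.seed``, so two agents with different
    parameters face identical outcome randomness per (trial, choice
    probability) comparison. Deterministic given both seeds.
    """
    agent.validate()
    choice_rng = np.random.default_rng([agent.seed, 0xC401CE])
    outcome_rng = np.random.default_rng([schedule.config.seed, 0xD0C0DE])

    q = {a: float(agent.q_init) for a in ACTIONS}
    choices: list[str] = []
    outcomes: list[int] = []
    for t in schedule.trial_index:
        p_a, _ = softmax_prob((q["A"], q["B"]), agent.beta)
        choice = "A" if choice_rng.random() < p_a else "B"
        reward = int(outcome_rng.random() < schedule.p_reward(int(t), choice))
        q[choice], _ = q_update(q[choice], reward, agent.alpha)
        choices.append(choice)
        outcomes.append(reward)

    trials = pd.DataFrame(
        {
            "trial_index": schedule.trial_index,
            "choice": choices,
            "outcome": outcomes,
        }
    )
    return BehaviorSession(trials=trials, schedule=schedule, agent=agent)


def simulate_fixed_policy(
    schedule: TaskSchedule, policy: str = "best", seed: int = 0
) -> BehaviorSession:
    """Play a deterministic policy against the schedule's contingencies.

    ``policy`` is 'best' (always the currently best action), 'worst',
    or a literal action 'A'/'B'. Useful for checking the empirical
    reward rate of the schedule itself.
    """
    if policy == "best":
        choices = schedule.best_action.copy()
    elif policy == "worst":
        choices = np.where(schedule.best_action == "A", "B", "A")
    elif policy in ACTIONS:
        choices = np.full(schedule.n_trials, policy, dtype="<U1")
    else:
        raise ValueError("policy must be 'best', 'worst', 'A' or 'B'")
    outcome_rng = np.random.default_rng([schedule.config.seed, 0xD0C0DE])
    p = np.where(choices == "A", schedule.p_reward_a, 1.0 - schedule.p_reward_a)
    outcomes = (outcome_rng.random(schedule.n_trials) < p).astype(int)
    trials = pd.DataFrame(
        {"trial_index": schedule.trial_index, "choice": choices, "outcome": outcomes}
    )
    return BehaviorSession(trials=trials, schedule=schedule)
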