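"""Two-parameter reinforcement-learning model of reversal-learning choice.

The model carries one expected value Q per action, updated after each
outcome by the delta rule

    Q_new = Q + alpha * (outcome - Q),

with the reward prediction error RPE = outcome - Q, and maps the value
difference onto choice probabilities through a softmax with inverse
temperature beta. alpha (RPE sensitivity / learning rate) and beta are
the two free parameters; they are estimated per session by multi-start
bounded maximum likelihood. The absolute RPE (absRPE) trace tracks the
unexpectedness of outcomes irrespective of valence and is the behavioral
quantity linked downstream to dopamine receptor occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .agents import BehaviorSession

__all__ = [
    "RLParams",
    "BehaviorSummary",
    "softmax_prob",
    "q_update",
    "negloglik",
    "rpe_trace",
    "fit_rl",
    "perseverance_errors",
    "summarize_behavior",
]

BETA_MAX = 30.0


@dataclass(frozen=True)
class RLParams:
    """Fitted model parameters for one session."""

    alpha: float
    beta: float
    neg_loglik: float
    convergence: bool
    n_restarts_used: int
    q_init: float = 0.5


@dataclass(frozen=True)
class BehaviorSummary:
    """Session-level behavioral summary around one reversal."""

    perseverance_errors: int
    mean_absrpe_post: float
    total_reward: float
    window_len: int = 25


def softmax_prob(q_pair: tuple[float, float], beta: float) -> tuple[float, float]:
    """Choice probabilities (p_A, p_B) from a pair of action values.

    Overflow-safe: computed through the logistic of beta*(q_A - q_B),
    and invariant to adding a constant to both values.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q_a, q_b = float(q_pair[0]), float(q_pair[1])
    if not (np.isfinite(q_a) and np.isfinite(q_b)):
        raise ValueError("q-values must be finite")
    p_a = float(expit(beta * (q_a - q_b)))
    return p_a, 1.0 - p_a


def q_update(q: float, outcome: int, alpha: float) -> tuple[float, float]:
    """Delta-rule update of the chosen action's value.

    Returns ``(q_new, rpe)`` with rpe = outcome - q.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rpe = float(outcome) - float(q)
    return float(q) + alpha * rpe, rpe


def _session_arrays(session: "BehaviorSession") -> tuple[np.ndarray, np.ndarray]:
    chose_a = session.choices == "A"
    return chose_a, session.outcomes


def negloglik(
    session: "BehaviorSession",
    alpha: float,
    beta: float,
    q_init: float = 0.5,
) -> float:
    """Negative log-likelihood (nats) of a session under (alpha, beta).

    Equals -sum_t log p(choice_t) with probabilities from the softmax
    over sequentially delta-rule-updated Q values.
    """
    chose_a, outcomes = _session_arrays(session)
    q_a = q_b = float(q_init)
    nll = 0.0
    for a_chosen, outcome in zip(chose_a, outcomes):
        dq = q_a - q_b if a_chosen else q_b - q_a
        # -log sigmoid(beta*dq), stable for large |beta*dq|
        nll += float(np.logaddexp(0.0, -beta * dq))
        if a_chosen:
            q_a += alpha * (outcome - q_a)
        else:
            q_b += alpha * (outcome - q_b)
    return nll


def rpe_trace(
    session: "BehaviorSession",
    alpha: float,
    beta: float,
    q_init: float = 0.5,
) -> pd.DataFrame:
    """Trial-wise model trace at fixed parameters.

    Columns: q_A, q_B (values *before* the trial's update), p_choice
    (probability of the made choice), rpe (signed) and abs_rpe.
    """
    chose_a, outcomes = _session_arrays(session)
    n = len(outcomes)
    out = {
        "trial_index": np.arange(1, n + 1),
        "q_A": np.empty(n),
        "q_B": np.empty(n),
        "p_choice": np.empty(n),
        "rpe": np.empty(n),
        "abs_rpe": np.empty(n),
    }
    q_a = q_b = float(q_init)
    for t in range(n):
        out["q_A"][t], out["q_B"][t] = q_a, q_b
        p_a, p_b = softmax_prob((q_a, q_b), beta)
        if chose_a[t]:
            out["p_choice"][t] = p_a
            rpe = outcomes[t] - q_a
            q_a += alpha * rpe
        else:
            out["p_choice"][t] = p_b
            rpe = outcomes[t] - q_b
            q_b += alpha * rpe
        out["rpe"][t] = rpe
        out["abs_rpe"][t] = abs(rpe)
    return pd.DataFrame(out)


def fit_rl(
    session: "BehaviorSession",
    n_restarts: int = 10,
    seed: int = 0,
    q_init: float = 0.5,
    beta_max: float = BETA_MAX,
) -> tuple[RLParams, pd.DataFrame]:
    """Fit (alpha, beta) by multi-start bounded maximum likelihood.

    L-BFGS-B from ``n_restarts`` seeded starting points over
    alpha in [0, 1], beta in [0, beta_max]; the restart with the lowest
    negative log-likelihood wins. Returns the fitted parameters and the
    trial-wise RPE trace at those parameters. Deterministic given seed.
    """
    if session.n_trials < 2 or len(np.unique(session.outcomes)) < 2:
        raise ValueError("session must contain >= 2 trials with distinct outcomes")
    rng = np.random.default_rng([seed, 0xF17])
    starts = np.column_stack(
        [rng.uniform(0.05, 0.95, n_restarts), rng.uniform(0.2, 0.8 * beta_max, n_restarts)]
    )

    def objective(theta: np.ndarray) -> float:
        return negloglik(session, theta[0], theta[1], q_init)

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, beta_max)],
        )
        any_converged = any_converged or bool(res.success)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:  # every restart failed: surface the flag, keep best effort
        res = minimize(
            objective,
            starts[0],
            method="Nelder-Mead",
            bounds=[(0.0, 1.0), (0.0, beta_max)],
        )
        best = res
    params = RLParams(
        alpha=float(best.x[0]),
        beta=float(best.x[1]),
        neg_loglik=float(best.fun),
        convergence=any_converged,
        n_restarts_used=n_restarts,
        q_init=q_init,
    )
    return params, rpe_trace(session, params.alpha, params.beta, q_init)


def perseverance_errors(session: "BehaviorSession", reversal_trial: int) -> int:
    """Number of consecutive post-reversal choices of the previously
    best action, ending at the first choice of the new best action.
    """
    if session.schedule is None:
        raise ValueError("session has no schedule attached")
    prev_best = session.schedule.best_action_before(reversal_trial)
    choices = session.choices[reversal_trial - 1 :]
    count = 0
    for c in choices:
        if c != prev_best:
            break
        count += 1
    return count


def summarize_behavior(
    session: "BehaviorSession",
    trace: pd.DataFrame,
    reversal_trial: int,
    window_len: int = 25,
    reward_value: float = 3.0,
) -> BehaviorSummary:
    """Summarize a session around one reversal.

    ``mean_absrpe_post`` is the mean absRPE over ``window_len`` trials
    starting at the reversal trial; ``total_reward`` is the session-wide
    accumulated reward in currency units.
    """
    if reversal_trial + window_len - 1 > session.n_trials:
        raise ValueError(
            f"window of {window_len} trials from trial {reversal_trial} "
            f"exceeds the {session.n_trials}-trial session"
        )
    window = trace["abs_rpe"].to_numpy()[reversal_trial - 1 : reversal_trial - 1 + window_len]
    return BehaviorSummary(
        perseverance_errors=perseverance_errors(session, reversal_trial),
        mean_absrpe_post=float(window.mean()),
        total_reward=float(session.outcomes.sum() * reward_value),
        window_len=window_len,
    )
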