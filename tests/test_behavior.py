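import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import revpet as rp
from revpet.behavior import negloglik, q_update, softmax_prob


def make_session(choices, outcomes, schedule=None):
    return rp.BehaviorSession(
        pd.DataFrame(
            {
                "trial_index": np.arange(1, len(choices) + 1),
                "choice": list(choices),
                "outcome": list(outcomes),
            }
        ),
        schedule=schedule,
    )


def naive_negloglik(choices, outcomes, alpha, beta, q_init=0.5):
    """Independent trial-by-trial re-enactment of the model likelihood."""
    q = {"A": q_init, "B": q_init}
    nll = 0.0
    for c, o in zip(choices, outcomes):
        ea, eb = np.exp(beta * q["A"]), np.exp(beta * q["B"])
        p = ea / (ea + eb) if c == "A" else eb / (ea + eb)
        nll -= np.log(p)
        q[c] = q[c] + alpha * (o - q[c])
    return nll


class TestSoftmax:
    def test_zero_beta_is_uniform(self):
        assert softmax_prob((0.9, 0.1), 0.0) == (0.5, 0.5)

    def test_large_beta_limit(self):
        p_a, p_b = softmax_prob((1.0, 0.0), 500.0)
        assert p_a == pytest.approx(1.0)

    def test_group_mean_beta_value(self):
        # direct evaluation at the human group-mean inverse temperature
        p_a, _ = softmax_prob((0.8, 0.2), 3.20)
        assert p_a == pytest.approx(1.0 / (1.0 + np.exp(-3.20 * 0.6)), rel=1e-12)

    def test_no_overflow_at_extreme_logits(self):
        with np.errstate(over="raise"):
            p_a, p_b = softmax_prob((700.0, 0.0), 1.0)
        assert p_a <= 1.0 and p_b >= 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        q=st.floats(-5, 5),
        dq=st.floats(-5, 5),
        shift=st.floats(-100, 100),
        beta=st.floats(0, 20),
    )
    def test_translation_invariance_and_normalization(self, q, dq, shift, beta):
        p = softmax_prob((q, q + dq), beta)
        p_shift = softmax_prob((q + shift, q + dq + shift), beta)
        assert p[0] + p[1] == pytest.approx(1.0)
        assert p[0] == pytest.approx(p_shift[0], abs=1e-9)


class TestQUpdate:
    @pytest.mark.parametrize(
        "q,outcome,alpha,expected_q,expected_rpe",
        [
            (0.7, 1, 0.0, 0.7, 0.3),
            (0.5, 1, 1.0, 1.0, 0.5),
            (0.5, 0, 0.38, 0.31, -0.5),  # at the human group-mean learning rate
        ],
    )
    def test_examples(self, q, outcome, alpha, expected_q, expected_rpe):
        q_new, rpe = q_update(q, outcome, alpha)
        assert q_new == pytest.approx(expected_q)
        assert rpe == pytest.approx(expected_rpe)

    def test_values_stay_in_unit_interval(self, session_04_5):
        trace = rp.rpe_trace(session_04_5, alpha=0.9, beta=2.0)
        assert trace[["q_A", "q_B"]].to_numpy().min() >= 0.0
        assert trace[["q_A", "q_B"]].to_numpy().max() <= 1.0
        assert np.allclose(trace["abs_rpe"], trace["rpe"].abs())


class TestNegLogLik:
    def test_zero_beta_equals_n_log_two(self, session_04_5):
        expected = session_04_5.n_trials * np.log(2.0)
        assert negloglik(session_04_5, 0.3, 0.0) == pytest.approx(expected)

    def test_three_trial_hand_worked(self):
        sess = make_session("AAB", [1, 0, 1])
        assert negloglik(sess, 0.5, 2.0) == pytest.approx(
            naive_negloglik("AAB", [1, 0, 1], 0.5, 2.0)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.sampled_from("AB"), st.integers(0, 1)), min_size=1, max_size=30
        ),
        alpha=st.floats(0, 1),
        beta=st.floats(0, 15),
    )
    def test_matches_naive_re_enactment(self, data, alpha, beta):
        choices = "".join(c for c, _ in data)
        outcomes = [o for _, o in data]
        sess = make_session(choices, outcomes)
        assert negloglik(sess, alpha, beta) == pytest.approx(
            naive_negloglik(choices, outcomes, alpha, beta), rel=1e-9
        )

    def test_true_parameters_beat_distant_ones_on_average(self, schedule):
        diffs = []
        for seed in range(10):
            sess = rp.simulate_agent(schedule, rp.AgentSpec(0.4, 5.0, seed=seed))
            diffs.append(negloglik(sess, 0.05, 0.3) - negloglik(sess, 0.4, 5.0))
        assert np.mean(diffs) > 0


class TestFit:
    def test_refit_reproduces_neg_loglik(self, session_04_5):
        params, _ = rp.fit_rl(session_04_5, seed=0)
        assert negloglik(session_04_5, params.alpha, params.beta) == pytest.approx(
            params.neg_loglik
        )

    def test_fit_deterministic(self, session_04_5):
        p1, _ = rp.fit_rl(session_04_5, seed=4)
        p2, _ = rp.fit_rl(session_04_5, seed=4)
        assert (p1.alpha, p1.beta, p1.neg_loglik) == (p2.alpha, p2.beta, p2.neg_loglik)

    def test_recovers_generating_parameters(self, schedule):
        errs_a, errs_b = [], []
        for seed in range(5):
            sess = rp.simulate_agent(schedule, rp.AgentSpec(0.4, 5.0, seed=100 + seed))
            p, _ = rp.fit_rl(sess, seed=seed)
            errs_a.append(abs(p.alpha - 0.4))
            errs_b.append(abs(p.beta - 5.0))
        assert np.median(errs_a) < 0.15
        assert np.median(errs_b) < 2.0

    def test_random_choices_give_near_zero_beta(self, schedule):
        sess = rp.simulate_agent(schedule, rp.AgentSpec(0.3, 0.0, seed=1))
        p, _ = rp.fit_rl(sess, seed=1)
        assert p.beta < 0.5

    def test_degenerate_session_raises(self):
        with pytest.raises(ValueError):
            rp.fit_rl(make_session("AAAA", [1, 1, 1, 1]))


class TestPerseveranceAndSummary:
    def test_three_then_switch(self, schedule):
        choices = ["A"] * 153 + ["B"] + ["A"] * 96
        sess = make_session(choices, [0] * 250, schedule)
        assert rp.perseverance_errors(sess, 151) == 3

    def test_immediate_switch_is_zero(self, schedule):
        choices = ["A"] * 150 + ["B"] * 100
        sess = make_session(choices, [0] * 250, schedule)
        assert rp.perseverance_errors(sess, 151) == 0

    def test_window_mean_matches_arithmetic(self, session_04_5):
        params, trace = rp.fit_rl(session_04_5, seed=0)
        summary = rp.summarize_behavior(session_04_5, trace, 151, window_len=25)
        manual = trace["abs_rpe"].to_numpy()[150:175].mean()
        assert summary.mean_absrpe_post == pytest.approx(manual)
        assert summary.total_reward == pytest.approx(session_04_5.outcomes.sum() * 3.0)
        assert summary.total_reward <= 250 * 3.0

    def test_truncated_window_raises(self, session_04_5):
        _, trace = rp.fit_rl(session_04_5, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            rp.summarize_behavior(session_04_5, trace, 240, window_len=25)


def test_fitted_alpha_anticorrelates_with_post_reversal_absrpe(schedule):
    """Subjects with higher RPE sensitivity re-learn faster and show a
    lower mean absRPE after the reversal (model-intrinsic coupling)."""
    alphas, absrpes = [], []
    rng = np.random.default_rng(12)
    for i in range(16):
        a = float(rng.uniform(0.1, 0.9))
        sess = rp.simulate_agent(schedule, rp.AgentSpec(a, 5.0, seed=200 + i))
        p, trace = rp.fit_rl(sess, seed=i)
        s = rp.summarize_behavior(sess, trace, 151)
        alphas.append(p.alpha)
        absrpes.append(s.mean_absrpe_post)
    assert np.corrcoef(alphas, absrpes)[0, 1] < 0
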