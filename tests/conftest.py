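import numpy as np
import pytest

import revpet as rp

REVERSAL_S = 2280.0  # first reversal: 8 min task onset + 30 min stable phase
SCAN_END_S = 4080.0


@pytest.fixture(scope="session")
def schedule():
    return rp.generate_schedule()


@pytest.fixture(scope="session")
def big_schedule():
    """>10^4 trials for empirical contingency checks."""
    cfg = rp.TaskConfig(n_trials=10050, stable_trials=10000, seed=3)
    return rp.generate_schedule(cfg)


@pytest.fixture(scope="session")
def session_04_5(schedule):
    return rp.simulate_agent(schedule, rp.AgentSpec(alpha=0.4, beta=5.0, seed=11))


@pytest.fixture(scope="session")
def clean_pair():
    """Noiseless baseline reference/target TAC pair (BP_ND = 2.5)."""
    return rp.simulate_tac(rp.TacSimSpec())


@pytest.fixture(scope="session")
def release_pair():
    """Noiseless pair with a 12%-peak-occupancy release at the reversal,
    peaking 2 min after onset."""
    gamma = rp.gamma_for_peak_occupancy(12.0, 0.35, 2.5)
    spec = rp.TacSimSpec(release=rp.ReleaseSpec(REVERSAL_S, REVERSAL_S + 120.0, gamma))
    return rp.simulate_tac(spec)


@pytest.fixture(scope="session")
def basis_set():
    return rp.build_reversal_basis(REVERSAL_S, scan_end_s=SCAN_END_S)


@pytest.fixture(scope="session")
def k2_prime(clean_pair):
    ref, tgt, _ = clean_pair
    return rp.mrtm_baseline_fit(tgt, ref).k2_prime_per_min


@pytest.fixture(scope="session")
def windows():
    return {"pre": (480.0, REVERSAL_S), "post": (REVERSAL_S, REVERSAL_S + 600.0)}
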