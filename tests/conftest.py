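import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def paradigm():
    return bs.generate_paradigm(seed=0)


@pytest.fixture(scope="session")
def small_gt():
    """3 well-separated states in 8 channels."""
    return bs.default_ground_truth(n_states=3, n_channels=8, seed=1)


@pytest.fixture(scope="session")
def reference_cohort_sessions():
    """The reduced reference scenario: 20 sessions x 400 timepoints x 30 channels,
    7 well-separated ground-truth states."""
    gt = bs.default_ground_truth(n_states=7, n_channels=30, seed=11)
    paradigm = bs.generate_paradigm(seed=0)
    rng = np.random.default_rng(7)
    sessions = [bs.simulate_session(gt, paradigm, T=400, seed=rng)[0] for _ in range(20)]
    return gt, sessions


@pytest.fixture(scope="session")
def reference_fit(reference_cohort_sessions):
    gt, sessions = reference_cohort_sessions
    model, stcs = bs.fit(sessions, K=7, n_init=2, max_iter=200, seed=5)
    return gt, sessions, model, stcs


@pytest.fixture(scope="session")
def demo_cohort():
    return bs.generate_cohort(bs.CohortDesign.demo(),
                              bs.default_ground_truth(n_states=4, n_channels=10, seed=3),
                              seed=42)
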