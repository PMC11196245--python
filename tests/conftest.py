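import numpy as np
import pandas as pd
import pytest

import synthtrial as st


@pytest.fixture(scope="session")
def small_schema() -> st.VariableSchema:
    return st.VariableSchema(
        (
            st.Variable("age", "continuous"),
            st.Variable("sex", "categorical"),
            st.Variable("pfs_time", "continuous", "pfs_time"),
            st.Variable("pfs_event", "integer", "pfs_event"),
            st.Variable("os_time", "continuous", "os_time"),
            st.Variable("os_event", "integer", "os_event"),
        )
    )


@pytest.fixture
def small_table(small_schema) -> st.TrialTable:
    df = pd.DataFrame(
        {
            "age": [55.0, 62.5, 71.0, 48.0],
            "sex": ["m", "f", "f", "m"],
            "pfs_time": [120.0, 80.0, 200.0, 45.0],
            "pfs_event": [1, 1, 0, 1],
            "os_time": [300.0, 80.0, 260.0, 150.0],
            "os_event": [1, 0, 0, 1],
        }
    )
    return st.TrialTable(small_schema, df)


@pytest.fixture(scope="session")
def actual_trial() -> st.TrialTable:
    """The reference simulated control arm (232 subjects)."""
    return st.simulate_trial(st.default_sim_config())


@pytest.fixture(scope="session")
def cart_model(actual_trial) -> st.SynthModel:
    return st.fit_synthesizer(actual_trial, "cart")


def random_survival_fixture(rng: np.random.Generator, n_min=20, n_max=80):
    """One random right-censored sample with a mix of tied and distinct times."""
    n = int(rng.integers(n_min, n_max))
    t = np.round(rng.weibull(1.2, n) * 100, 0) + 1.0
    e = (rng.random(n) < 0.75).astype(int)
    if e.sum() == 0:  # keep at least one event for the two-sample statistics
        e[0] = 1
    return t, e
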