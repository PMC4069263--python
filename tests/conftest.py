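import numpy as np
import pandas as pd
import pytest

from switchscan import (CohortSimConfig, ExprSimConfig, generate_cohorts,
                        generate_expression)


@pytest.fixture(scope="session")
def small_sim():
    """A modest noise-bearing simulation shared across read-only tests."""
    config = ExprSimConfig(n_genes=120, delta=2.0, sigma=0.25, seed=7)
    matrix, truth = generate_expression(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def small_cohorts():
    config = CohortSimConfig(n_flies=400, seed=11)
    events, truth = generate_cohorts(config)
    return config, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_events(death_days, censor_days=(), cohort="CF"):
    """Build an event frame from explicit per-fly day lists."""
    rows = [(f"{cohort}_{i}", cohort, int(d), "death")
            for i, d in enumerate(death_days)]
    rows += [(f"{cohort}_c{i}", cohort, int(d), "censored")
             for i, d in enumerate(censor_days)]
    return pd.DataFrame(rows, columns=["fly_id", "cohort", "day", "status"])
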