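"""Shared fixtures: cost ensembles and small decoded cohorts, built once."""

import numpy as np
import pytest

from errpref.pipeline import run_cohort, simulate_trial_table


@pytest.fixture(scope="session")
def trial_costs():
    """A 400-trial (rho, s) cost ensemble from the default workspace."""
    rng = np.random.default_rng(1234)
    return simulate_trial_table(400, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """Five decoded subjects at 200 trials — enough for direction checks."""
    return run_cohort(n_subjects=5, n_trials=200, seed=7)
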