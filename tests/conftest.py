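"""Shared fixtures. The expensive end-to-end artifacts (parameter-recovery
runs, the scenario table) are session-scoped so several tests can share one
computation."""

import numpy as np
import pytest

from rispkpd import default_parameters
from rispkpd.datasets import default_study_designs, generate_dataset
from rispkpd.experiments import btp_experiment, recovery_experiment
from rispkpd.simulate import SCENARIOS

#: fixed seed for every stochastic end-to-end run in the suite
SUITE_SEED = 1


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def designs():
    return default_study_designs()


@pytest.fixture(scope="session")
def small_dataset(params, designs):
    """Multiplier-1 synthetic dataset (282 animals) under full variability."""
    return generate_dataset(designs, params, seed=SUITE_SEED, multiplier=1)


@pytest.fixture(scope="session")
def headline_recovery(params):
    """The multiplier-10 parameter-recovery run (generate -> fit -> compare)."""
    return recovery_experiment(params, multiplier=10, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def recovery_mult2(params):
    """Same experiment at multiplier 2, for the consistency comparison."""
    return recovery_experiment(params, multiplier=2, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def btp_table(params):
    """Brain-to-plasma ratios for every scenario over the design arms."""
    return btp_experiment(params, list(SCENARIOS))
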