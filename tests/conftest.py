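import dataclasses

import numpy as np
import pytest

from trialcea import TrialConfig, generate_trial
from trialcea.synthetic_data import default_cost_distributions


def low_noise_config(n_per_arm: int, seed: int, dropout=(0.0, 0.0)) -> TrialConfig:
    """Config with strong arm effects and low heterogeneity.

    Used for parameter-recovery and coverage experiments where Monte
    Carlo error must be small relative to the configured increments.
    """
    cats = {
        name: dataclasses.replace(cm, shape=30.0)
        for name, cm in default_cost_distributions().items()
    }
    return TrialConfig(
        n_per_arm=n_per_arm,
        baseline_phq_sd=3.0,
        whodas_concentration=300.0,
        whodas_item_means={
            "ST": {0: 2.0, 3: 1.6, 12: 1.4},
            "T+P": {0: 2.0, 3: 0.8, 12: 0.4},
        },
        cost_distributions=cats,
        cost_severity_coupling=0.05,
        dropout_prob={"ST": dropout[0], "T+P": dropout[1]},
        seed=seed,
    )


@pytest.fixture
def small_config():
    return TrialConfig(n_per_arm=20, seed=42)


@pytest.fixture
def small_trial(small_config):
    return generate_trial(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
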