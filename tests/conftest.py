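import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ignet.synthetic import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    config = SimConfig(n_subjects=60, n_ad_target=28, n_snps=40,
                       causal_log_odds=1.0, seed=11)
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_predictions(labels, scores):
    """Prediction-set DataFrame from parallel label/score sequences."""
    labels = np.asarray(labels)
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(len(labels))],
        "p_ad": np.asarray(scores, dtype=float),
        "label": labels,
    })
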