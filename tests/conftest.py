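import numpy as np
import pandas as pd
import pytest

from radsurv import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (110 patients, 107 features), seed 7."""
    return generate_cohort(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with batch distortions switched off (identity batch effects)."""
    cfg = SimulationConfig(gamma_sd=0.0, delta_range=(1.0, 1.0))
    return generate_cohort(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, censor_frac=0.3, tie_prob=0.0):
    """Small random survival data for property tests (ties optional)."""
    time = rng.exponential(10, size=n).round(3) + 0.5
    if tie_prob > 0:
        # force duplicated times
        k = max(1, int(tie_prob * n))
        time[rng.integers(0, n, size=k)] = time[rng.integers(0, n)]
    event = (rng.random(n) > censor_frac).astype(int)
    return pd.DataFrame({"time": time, "event": event})
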