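import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dcapipe as dp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fixed per-class seed offsets so every suite draws the same instances
CLASS_OFFSET = {"full": 1, "partial": 2, "split": 3, "absent": 4}


@pytest.fixture(scope="session")
def small_sim():
    """300-gene simulated experiment with planted effects, 3 replicates."""
    return dp.simulate_counts(
        dp.SimDesign(n_genes=300, replicates_per_cell=3, seed=11), dp.EffectSpec()
    )


@pytest.fixture(scope="session")
def small_fit(small_sim):
    return dp.MultifactorDE(small_sim.counts, small_sim.samples).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_corr_frame(rng, n, m_timepoints=6, prefix="g"):
    """A valid Pearson correlation matrix from random profiles."""
    profiles = pd.DataFrame(
        rng.normal(size=(n, m_timepoints)),
        index=[f"{prefix}{i}" for i in range(n)],
    )
    return dp.correlation_matrix(profiles)
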