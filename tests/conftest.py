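import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mirtempo as mt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_small():
    """A small three-group experiment with default module occupancies."""
    cfg = mt.SimConfig(n_features=200, lib_size_mean=2e5, seed=11)
    counts, design, truth = mt.simulate_experiment(cfg)
    return counts, design, truth


@pytest.fixture()
def toy_counts():
    """Deterministic 6-feature, 4-sample matrix with equal library sizes."""
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        rng.poisson(40, size=(6, 4)),
        index=[f"miR-t{i}-5p" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
    totals = counts.sum(axis=0)
    counts.iloc[-1] += (totals.max() - totals).to_numpy()  # equalize libraries
    return counts
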