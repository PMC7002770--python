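import numpy as np
import pandas as pd
import pytest

import oxiscan as ox


@pytest.fixture(scope="session")
def small_cohort() -> ox.CohortBundle:
    """8 types x 30 samples with planted effects; shared across tests."""
    cfg = ox.SimConfig(n_cancer_types=8, samples_per_type=30, seed=11)
    return ox.generate_cohort(cfg)


@pytest.fixture(scope="session")
def grouped_frame():
    """Plain grouped regression data with a known mixed structure."""
    rng = np.random.default_rng(42)
    n, q = 200, 8
    g = rng.integers(0, q, n)
    x = rng.normal(size=n)
    purity = rng.uniform(0.3, 1.0, n)
    u = rng.normal(0, 1.2, q)
    y = 1.0 + 0.5 * x - 0.8 * purity + u[g] + rng.normal(0, 0.9, n)
    return pd.DataFrame({
        "y": y, "x": x, "purity": purity,
        "g": [f"g{i}" for i in g]})
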