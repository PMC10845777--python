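import numpy as np
import pandas as pd
import pytest

from no2burden import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_sim():
    """A 4-county, 2-year synthetic world with the effect concentrated at
    lag 0 (shared across tests; never mutated)."""
    cfg = SimulationConfig(
        n_urban_counties=2, n_rural_counties=2, n_years=2,
        lag_weights=(1.0, 0.0, 0.0, 0.0, 0.0), seed=2024,
    )
    return cfg, simulate_panel(cfg)


@pytest.fixture()
def county_frame(small_sim):
    _, sim = small_sim
    return sim.panel[sim.panel.county_id == "U01"].reset_index(drop=True)


@pytest.fixture(scope="session")
def glm_fixture():
    """A 50-row Poisson regression problem with a known design."""
    rng = np.random.default_rng(7)
    n = 50
    x1 = rng.normal(size=n)
    x2 = rng.uniform(-1, 1, size=n)
    X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2})
    beta = np.array([1.2, 0.3, -0.5])
    y = rng.poisson(np.exp(X.to_numpy() @ beta))
    return y, X
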