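import numpy as np
import pandas as pd
import pytest

from yieldgap.simulate import ScenarioConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 120-unit default-scenario panel shared across read-only tests."""
    cfg = ScenarioConfig(n_units=120, seed=42)
    records, unit_cov, truth = generate_panel(cfg)
    return cfg, records, unit_cov, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_records(n=50, seed=0, yield_loc=5.0, yield_scale=0.5, crop="maize", year=2000):
    """Plain single-crop-year census table with Gaussian yields."""
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "unit_id": [f"A{i:03d}" for i in range(n)],
            "crop": crop,
            "year": year,
            "yield_t_ha": np.abs(r.normal(yield_loc, yield_scale, n)),
            "area_ha": r.lognormal(5.0, 1.0, n),
            "area_fraction": r.uniform(0.2, 1.5, n),
        }
    )
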