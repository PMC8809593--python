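import numpy as np
import pandas as pd
import pytest

import croptail as ct


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_panel():
    """Raw panel for one region (6 countries x 42 years) with a little missingness."""
    spec = ct.SyntheticSpec(family="gaussian", rho=0.6, n_countries=6, n_years=42,
                            missing_rate=0.04, seed=42)
    panel, truth = ct.gen_region_fixture(spec, region="Eastern Africa")
    return panel, truth


@pytest.fixture(scope="session")
def region_map():
    return ct.read_region_map()


@pytest.fixture(scope="session")
def laplace_gaussian_pair():
    """Large Gaussian-copula pair already on exact Laplace margins (rho=0.7)."""
    spec = ct.SyntheticSpec(family="gaussian", rho=0.7, n=50000, marginal="laplace", seed=0)
    pair, truth = ct.gen_pair(spec)
    return pair, truth


def make_records(rows):
    """Build a raw panel frame from (country, year, yield, prec, tmin, tmax) tuples."""
    return pd.DataFrame(
        [{"country": c, "year": y, "crop": "maize",
          "yield": yl, "prec": p, "tmin": tn, "tmax": tx}
         for (c, y, yl, p, tn, tx) in rows]
    )
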