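import logging

import numpy as np
import pandas as pd
import pytest

from ringphys.io import RingWidthSeries
from ringphys.simulate import SimulationConfig, simulate_atmosphere, simulate_climate

# keep expected-warning noise out of the test log
logging.getLogger("ringphys").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced tree counts: fast but still >= 5 trees per model."""
    return SimulationConfig(
        seed=11,
        n_isotope_trees={"Certovo": 6, "Plesne": 3},
        n_increment_trees={"Certovo": 12, "Plesne": 12},
    )


@pytest.fixture(scope="session")
def atmosphere(small_config) -> pd.DataFrame:
    return simulate_atmosphere(small_config)


@pytest.fixture(scope="session")
def climate(small_config) -> pd.DataFrame:
    return simulate_climate(small_config)


@pytest.fixture
def linear_atmosphere() -> pd.DataFrame:
    years = np.arange(1900, 2012)
    return pd.DataFrame(
        {
            "year": years,
            "d13c_air": -6.5 - 0.01 * (years - 1900),
            "ca_ppm": 300.0 + 0.5 * (years - 1900),
        }
    )


def make_series(tree_id="T1", site="Certovo", first_year=1850, widths=None, pith=2.0):
    if widths is None:
        rng = np.random.default_rng(abs(hash(tree_id)) % 2**31)
        widths = np.round(rng.uniform(0.3, 3.0, 120), 2)
    return RingWidthSeries(
        tree_id=tree_id, site=site, first_year=first_year,
        widths=np.asarray(widths, dtype=float), pith_offset_mm=pith,
    )


@pytest.fixture
def series_factory():
    return make_series
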