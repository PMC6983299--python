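import numpy as np
import pytest

import vegtrend as vt


@pytest.fixture
def noiseless_fixture() -> vt.AnnualSeries:
    """Staged piecewise trend 1981-2018: +0.0016, -0.0025, +0.0033 per year."""
    return vt.default_ndvi_fixture()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_series(values, start_year=1981, name="x") -> vt.AnnualSeries:
    values = np.asarray(values, dtype=float)
    years = np.arange(start_year, start_year + values.size)
    return vt.AnnualSeries(years, values, name)
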