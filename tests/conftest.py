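import numpy as np
import pandas as pd
import pytest

from aqhealth.core import ConcentrationField, DomainSpec, PopulationGrid
from aqhealth import synth


@pytest.fixture(scope="session")
def small_domain() -> DomainSpec:
    """4x5 cells at 0.5 degrees, three whole days of hours."""
    return DomainSpec(
        lon_min=0.0, lon_max=2.5, lat_min=45.0, lat_max=47.0,
        resolution=0.5,
        time_start=pd.Timestamp("2010-01-01"),
        time_end=pd.Timestamp("2010-01-04"),
    )


@pytest.fixture(scope="session")
def month_domain() -> DomainSpec:
    """6x6 cells, two calendar months of hours (for monthly statistics)."""
    return DomainSpec(
        lon_min=0.0, lon_max=1.5, lat_min=45.0, lat_max=46.5,
        resolution=0.25,
        time_start=pd.Timestamp("2010-01-01"),
        time_end=pd.Timestamp("2010-03-01"),
    )


@pytest.fixture(scope="session")
def population(small_domain) -> PopulationGrid:
    return synth.generate_population(
        small_domain, total_population=1_000_000, n_hotspots=2, seed=11
    )


def make_field(domain, pollutant="PM25", value=10.0, values=None, **kwargs):
    if values is None:
        values = np.full((domain.n_hours, domain.n_lat, domain.n_lon), value)
    return ConcentrationField(domain=domain, pollutant=pollutant,
                              values=values, **kwargs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100101)
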