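import pandas as pd
import pytest
from hypothesis import settings

from holcbio import synthetic

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_region():
    """Two cities, four neighborhoods per grade: fast but fully structured."""
    cfg = synthetic.RegionConfig(
        n_cities=2, neighborhoods_per_grade_per_city=4, effort_mean=60,
        grid_cell_km=0.5,
    )
    return synthetic.make_region(cfg, seed=101)


@pytest.fixture(scope="session")
def small_records(small_region):
    comm = synthetic.CommunityConfig(effort_mean=60)
    return synthetic.simulate_observation_records(small_region, comm, seed=102)


@pytest.fixture(scope="session")
def small_assigned(small_records):
    """Records in ingest-side columns with ground-truth neighborhood ids."""
    return synthetic.as_ingested(small_records)


def make_records_frame(species, dates=None, **overrides):
    """Minimal hand-built ingest-style record frame for unit tests."""
    n = len(species)
    base = {
        "record_id": [str(i) for i in range(n)],
        "observed_on": pd.to_datetime(dates if dates is not None
                                      else ["2018-01-01"] * n),
        "latitude": [0.5] * n,
        "longitude": [0.5] * n,
        "species": species,
        "clade": ["bird"] * n,
        "quality": ["research"] * n,
        "native": ["native"] * n,
        "neighborhood_id": ["nb1"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)
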