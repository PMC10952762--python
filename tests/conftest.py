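import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bioassess.simulate import (SimConfig, generate_dataset,
                                generate_score_table_fixtures)
from bioassess.types import BioSample, HydroSeries, ScoreTable


@pytest.fixture(scope="session")
def score_tables():
    """Synthetic ~60-taxon score-table set shared across tests."""
    tables, sensitivity = generate_score_table_fixtures(60, seed=11)
    return tables


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic bundle (2 sites, 1 year, strong)."""
    config = SimConfig(n_sites=2, n_years=1, sonde_resolution_min=30,
                       determinands=("DO", "discharge", "turbidity"),
                       effect_preset="strong", seed=5)
    return generate_dataset(config)


def make_sample(counts, season="spring", site="siteA", rep="A",
                date=None):
    if date is None:
        date = {"spring": dt.date(2011, 4, 20),
                "summer": dt.date(2011, 7, 20),
                "autumn": dt.date(2011, 10, 20)}[season]
    return BioSample(site_id=site, sample_date=date, season=season,
                     replicate_id=rep, counts=counts)


def make_series(values, start="2011-06-01", resolution=15, site="siteA",
                determinand="DO"):
    values = np.asarray(values, dtype=float)
    t0 = np.datetime64(start, "ns")
    stamps = t0 + (np.arange(len(values)) * resolution * 60e9
                   ).astype("timedelta64[ns]")
    return HydroSeries(site_id=site, determinand=determinand,
                       timestamps=stamps, values=values,
                       nominal_resolution=resolution)


@pytest.fixture
def whpt_flat_table():
    """WHPT table whose class scores are flat (class-independent)."""
    entries = pd.DataFrame(
        {"s1": [10.0, 4.0], "s2": [10.0, 4.0],
         "s3": [10.0, 4.0], "s4": [10.0, 4.0]},
        index=pd.Index(["mayfly", "worm"], name="taxon_id"))
    return ScoreTable("WHPT", entries)
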