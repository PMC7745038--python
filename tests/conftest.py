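import numpy as np
import pytest
from shapely.geometry import box

from divgrid.occurrences import OccurrenceRecord, OccurrenceSet, ThreatCategory
from divgrid.synthetic_data import bias_scenario, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_country_100km():
    """A 100 x 100 km square country in planar metres."""
    return box(0.0, 0.0, 100_000.0, 100_000.0)


def make_occurrences(rows, crs_tag="planar"):
    """Build an OccurrenceSet from (species, class, x, y, year, g, n) tuples.

    Trailing fields may be omitted: year defaults to 2000 and both threat
    categories to NE.
    """
    records = []
    for row in rows:
        species, group, x, y = row[:4]
        year = row[4] if len(row) > 4 else 2000
        sg = ThreatCategory(row[5]) if len(row) > 5 else ThreatCategory.NE
        sn = ThreatCategory(row[6]) if len(row) > 6 else ThreatCategory.NE
        records.append(
            OccurrenceRecord(species, group, float(x), float(y), year, sg, sn)
        )
    return OccurrenceSet.from_records(records, crs_tag=crs_tag)


@pytest.fixture(scope="session")
def small_city_sim():
    """One small city-biased synthetic dataset shared across tests."""
    cfg = bias_scenario(
        "city",
        seed=7,
        n_records=3000,
        n_species={"Amphibia": 12, "Reptilia": 15, "Aves": 45, "Mammalia": 18},
        country_km=(200.0, 150.0),
    )
    return generate(cfg)
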