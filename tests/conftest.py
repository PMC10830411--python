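import numpy as np
import pandas as pd
import pytest

from lifecyclegeo import occurrences as occ
from lifecyclegeo import traits as traitmod
from lifecyclegeo.synth import SyntheticWorldConfig, generate_world

ALL_DIRTY = {
    "missing_coords": 0.02,
    "uncertainty": 0.02,
    "event_year": 0.02,
    "taxon_rank": 0.02,
    "basis_of_record": 0.02,
    "out_of_region": 0.02,
}


@pytest.fixture(scope="session")
def small_world():
    """A modest dirty world reused by read-only tests."""
    cfg = SyntheticWorldConfig(
        n_regions=20,
        grid_shape=(10, 10),
        n_species=400,
        n_years=6,
        seed=11,
        dirty_fractions=dict(ALL_DIRTY),
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_world_traits(small_world):
    species, report = traitmod.build_species_traits(
        small_world.trait_entries, small_world.synonym_table, small_world.crop_list
    )
    return species


@pytest.fixture(scope="session")
def small_world_proportions(small_world, small_world_traits):
    clean, _ = occ.clean_occurrences(small_world.occurrences)
    assigned, _ = occ.assign_regions(clean, small_world.region_map)
    matrix = occ.call_presence(assigned, small_world_traits)
    return occ.compute_proportions(matrix)


def make_occurrences(rows):
    """Build an occurrence table from (species, lon, lat, unc, basis, year, rank) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "lon",
            "lat",
            "coordinate_uncertainty",
            "basis_of_record",
            "event_year",
            "taxon_rank",
        ],
    )


def clean_row(species="Aa bb", lon=5.0, lat=7.0, unc=100.0, basis="HUMAN_OBSERVATION", year=2000, rank="SPECIES"):
    return (species, lon, lat, unc, basis, year, rank)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
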