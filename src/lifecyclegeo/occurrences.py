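"""Occurrence cleaning, region assignment, presence calling and proportions.

Raw occurrence points (GBIF-style rows) are unreliable at the individual
record level, so the pipeline works at the grain of regions: points are
filtered through a battery of quality checks, assigned to regions
(ecoregion polygons or equal-area grid cells), and converted to a
region x species presence matrix under an establishment rule — a species
counts as present only with at least 5 cleaned observations, and a region
enters the analysis only with at least 10 present species. Regional annual
proportions (among all species and among herbaceous species) are the
response variable of every downstream model.

Occurrence tables are pandas DataFrames with columns ``species``, ``lon``,
``lat``, ``coordinate_uncertainty`` (metres, NaN allowed),
``basis_of_record``, ``event_year`` (NaN allowed) and ``taxon_rank``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.strtree import STRtree

from ._geometry import cylindrical_equal_area

MAX_UNCERTAINTY_M = 100_000.0  # 100 km coordinate-uncertainty cutoff
MIN_EVENT_YEAR = 1946  # records during or before 1945 are unreliable
EXCLUDED_BASES = ("LITERATURE", "LIVING_SPECIMEN")  # museum/garden locations
PRESENCE_MIN_OBS = 5
REGION_MIN_SPECIES = 10

GBIF_COLUMNS = {
    "species": "species",
    "decimalLongitude": "lon",
    "decimalLatitude": "lat",
    "coordinateUncertaintyInMeters": "coordinate_uncertainty",
    "basisOfRecord": "basis_of_record",
    "eventDate": "event_date",
    "taxonRank": "taxon_rank",
}


# --- coordinate-validity battery -------------------------------------------
# Pluggable predicate checks for corrupt coordinates (zero-zero points,
# equal lat/lon from column swaps, out-of-range values). Each predicate maps
# a record table to a boolean mask of *bad* rows and assumes coordinates are
# non-null (missing coordinates are caught by their own filter first).

def _check_out_of_range(df: pd.DataFrame) -> pd.Series:
    return (df["lon"].abs() > 180) | (df["lat"].abs() > 90)


def _check_zero_zero(df: pd.DataFrame) -> pd.Series:
    return (df["lon"] == 0) & (df["lat"] == 0)


def _check_equal_lon_lat(df: pd.DataFrame) -> pd.Series:
    return (df["lon"] == df["lat"]) & (df["lon"] != 0)


DEFAULT_COORD_CHECKS: tuple[tuple[str, Callable[[pd.DataFrame], pd.Series]], ...] = (
    ("coord_out_of_range", _check_out_of_range),
    ("coord_zero_zero", _check_zero_zero),
    ("coord_equal_lon_lat", _check_equal_lon_lat),
)


@dataclass
class CleaningReport:
    """Per-filter removal tallies; every input record is attributed to the
    first filter it fails, so ``n_input == n_output + sum(removed)``."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_output + sum(self.removed.values())


def clean_occurrences(
    records: pd.DataFrame,
    max_uncertainty_m: float = MAX_UNCERTAINTY_M,
    min_event_year: int = MIN_EVENT_YEAR,
    drop_null_year: bool = True,
    coord_checks: Sequence[tuple[str, Callable[[pd.DataFrame], pd.Series]]] = DEFAULT_COORD_CHECKS,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Filter unreliable occurrence records.

    A record survives iff it has coordinates that pass the validity battery,
    a coordinate uncertainty of at most 100 km (or none reported), a basis
    of record that is not literature or living specimen, an event year after
    1945 (records with no year are removed by default; set
    ``drop_null_year=False`` to keep them), and a taxon rank of species.

    Removal is attributed to the first failing filter, in the order:
    missing coordinates, each coordinate check, uncertainty, basis of
    record, event year, taxon rank.
    """
    df = records.reset_index(drop=True)
    removed: dict[str, int] = {}
    alive = pd.Series(True, index=df.index)

    def apply(name: str, bad: pd.Series) -> None:
        hit = alive & bad.fillna(False).astype(bool)
        removed[name] = int(hit.sum())
        alive.loc[hit] = False

    apply("missing_coords", df["lon"].isna() | df["lat"].isna())
    for name, check in coord_checks:
        bad = pd.Series(False, index=df.index)
        has_coords = ~(df["lon"].isna() | df["lat"].isna())
        bad.loc[has_coords] = check(df.loc[has_coords])
        apply(name, bad)
    apply("uncertainty", df["coordinate_uncertainty"] > max_uncertainty_m)
    basis = df["basis_of_record"].astype(str).str.upper().str.replace(" ", "_")
    apply("basis_of_record", basis.isin(EXCLUDED_BASES))
    year_bad = df["event_year"] < min_event_year
    if drop_null_year:
        year_bad = year_bad | df["event_year"].isna()
    apply("event_year", year_bad)
    apply("taxon_rank", df["taxon_rank"].astype(str).str.upper() != "SPECIES")

    out = df[alive].reset_index(drop=True)
    report = CleaningReport(n_input=len(df), n_output=len(out), removed=removed)
    return out, report


# --- regions ----------------------------------------------------------------

class RegionMap:
    """A set of non-overlapping region polygons in lon/lat space.

    Points on a shared boundary are assigned deterministically to the
    covering region with the lowest id.
    """

    def __init__(self, polygons: dict[int, shapely.Geometry]):
        if not polygons:
            raise ValueError("empty region map")
        for rid, poly in polygons.items():
            if not poly.is_valid:
                raise ValueError(f"invalid geometry for region {rid}")
        self.polygons = dict(sorted(polygons.items()))
        self._ids = np.array(list(self.polygons.keys()))
        self._tree = STRtree(list(self.polygons.values()))

    @classmethod
    def from_geojson(cls, obj: dict) -> "RegionMap":
        polys = {}
        for feat in obj["features"]:
            polys[int(feat["properties"]["region"])] = shapely_shape(feat["geometry"])
        return cls(polys)

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "properties": {"region": int(rid)},
                "geometry": shapely.geometry.mapping(poly),
            }
            for rid, poly in self.polygons.items()
        ]
        return {"type": "FeatureCollection", "features": feats}

    def assign(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Region id per point; -1 for points outside every region."""
        pts = shapely.points(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))
        pt_idx, tree_idx = self._tree.query(pts, predicate="covered_by")
        out = np.full(len(pts), -1, dtype=int)
        if len(pt_idx):
            # lowest region id wins on shared boundaries
            cand = pd.DataFrame({"pt": pt_idx, "region": self._ids[tree_idx]})
            best = cand.groupby("pt")["region"].min()
            out[best.index.to_numpy()] = best.to_numpy()
        return out


def assign_regions(records: pd.DataFrame, region_map: RegionMap) -> tuple[pd.DataFrame, int]:
    """Attach a ``region`` column; drop and count points outside all regions."""
    df = records.reset_index(drop=True).copy()
    df["region"] = region_map.assign(df["lon"].to_numpy(), df["lat"].to_numpy())
    n_outside = int((df["region"] == -1).sum())
    df = df[df["region"] != -1].reset_index(drop=True)
    return df, n_outside


def gridify(records: pd.DataFrame, cell_km: float = 100.0) -> pd.DataFrame:
    """Assign records to equal-area square grid cells instead of ecoregions.

    Cells are ``cell_km`` x ``cell_km`` squares in a cylindrical equal-area
    projection, with half-open intervals [x, x+w) so every point falls in
    exactly one cell. The returned table carries the cell id in ``region``
    so the presence/proportion machinery applies unchanged.
    """
    df = records.reset_index(drop=True).copy()
    x, y = cylindrical_equal_area(df["lon"].to_numpy(), df["lat"].to_numpy())
    ix = np.floor(x / cell_km).astype(np.int64)
    iy = np.floor(y / cell_km).astype(np.int64)
    # dense, deterministic cell ids ordered by (ix, iy)
    cells = pd.MultiIndex.from_arrays([ix, iy]).unique().sortlevel([0, 1])[0]
    cell_id = {key: i for i, key in enumerate(cells)}
    df["region"] = [cell_id[(a, b)] for a, b in zip(ix, iy)]
    return df


# --- presence and proportions ----------------------------------------------

@dataclass
class PresenceMatrix:
    """Region x species observation counts with derived presence calls.

    ``table`` has one row per (region, species-with-trait-data) pair with
    columns count, present, life_cycle, growth_form.
    """

    table: pd.DataFrame
    min_obs: int = PRESENCE_MIN_OBS
    min_species: int = REGION_MIN_SPECIES

    def region_sufficiency(self, herbs_only: bool = False) -> pd.Series:
        """Whether each region has >= min_species present species (optionally
        counting herbaceous species only, the denominator of the
        annual-among-herbs analysis)."""
        t = self.table[self.table["present"]]
        if herbs_only:
            t = t[t["growth_form"] == "herbaceous"]
        n = t.groupby("region")["species"].nunique()
        n = n.reindex(self.table["region"].unique(), fill_value=0)
        return (n >= self.min_species).sort_index()


def call_presence(
    records: pd.DataFrame,
    species_traits: pd.DataFrame,
    min_obs: int = PRESENCE_MIN_OBS,
    min_species: int = REGION_MIN_SPECIES,
) -> PresenceMatrix:
    """Count observations per (region, species) and call presence.

    Only species with consensus trait data participate. Presence requires
    ``min_obs`` observations in the region (an established-population
    heuristic, not a single stray point).
    """
    traits = species_traits.set_index("accepted_name")[["life_cycle", "growth_form"]]
    df = records[records["species"].isin(traits.index)]
    counts = df.groupby(["region", "species"], sort=True).size().rename("count").reset_index()
    counts["present"] = counts["count"] >= min_obs
    counts = counts.join(traits, on="species")
    return PresenceMatrix(table=counts, min_obs=min_obs, min_species=min_species)


def compute_proportions(matrix: PresenceMatrix) -> pd.DataFrame:
    """Annual proportions per region, among all species and among herbs.

    Returns a DataFrame indexed by region with counts and proportions.
    ``p_annual`` is defined only for regions with >= 10 present species
    (``sufficient_all``); ``p_annual_herb`` only for regions with >= 10
    present *herbaceous* species (``sufficient_herb``); insufficient cells
    are NaN. Woody species never contribute to the herb denominator; species
    of unknown growth form contribute to the all-species analysis only.
    """
    t = matrix.table[matrix.table["present"]]
    herbs = t[t["growth_form"] == "herbaceous"]
    out = pd.DataFrame(
        {
            "n_species": t.groupby("region")["species"].nunique(),
            "n_annual": t[t["life_cycle"] == "annual"].groupby("region")["species"].nunique(),
            "n_herb_species": herbs.groupby("region")["species"].nunique(),
            "n_annual_herb": herbs[herbs["life_cycle"] == "annual"].groupby("region")["species"].nunique(),
        }
    ).fillna(0).astype(int)
    out.index.name = "region"
    out["sufficient_all"] = out["n_species"] >= matrix.min_species
    out["sufficient_herb"] = out["n_herb_species"] >= matrix.min_species
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p_annual"] = np.where(out["sufficient_all"], out["n_annual"] / out["n_species"], np.nan)
        out["p_annual_herb"] = np.where(
            out["sufficient_herb"], out["n_annual_herb"] / out["n_herb_species"], np.nan
        )
    return out.sort_index()


# --- GBIF-style IO ----------------------------------------------------------

def read_gbif_tsv(path) -> pd.DataFrame:
    """Read a GBIF-style tab-separated occurrence table into pipeline columns."""
    raw = pd.read_csv(path, sep="\t", dtype={"eventDate": str})
    df = raw.rename(columns=GBIF_COLUMNS)[list(GBIF_COLUMNS.values())]
    df["event_year"] = pd.to_numeric(df["event_date"].str.slice(0, 4), errors="coerce")
    return df.drop(columns=["event_date"])


def write_gbif_tsv(records: pd.DataFrame, path) -> None:
    """Write pipeline occurrence columns back to GBIF-style headers."""
    df = records.copy()
    year = df["event_year"]
    df["event_date"] = year.map(lambda y: "" if pd.isna(y) else f"{int(y)}-06-15")
    inv = {v: k for k, v in GBIF_COLUMNS.items()}
    out = df[list(GBIF_COLUMNS.values())].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)
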