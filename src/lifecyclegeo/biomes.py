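"""Whittaker-biome assignment in climate space and biome-level aggregation.

Each analysable region is located in the plane spanned by mean annual
temperature (degC) and total annual precipitation, and assigned to the
biome polygon containing it. Three cases arise:

* ``interior`` — the point lies strictly inside exactly one polygon;
* ``plurality-circle`` — the point sits on (or numerically at) a boundary;
  a circle around it is enlarged stepwise until one biome holds a strict
  plurality of the circle's intersected area;
* ``nearest`` — the point is outside every polygon (beyond the diagram's
  climate envelope) and takes the closest biome by Euclidean distance in
  raw axis units.

Presence is then re-called at biome level by pooling raw observation
counts of all member regions *before* applying the 5-observation rule, so
a species scattered thinly across a biome can be present in the biome
while absent from each single region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import shapely
from shapely.geometry import Point, shape as shapely_shape

from .occurrences import (
    PRESENCE_MIN_OBS,
    REGION_MIN_SPECIES,
    PresenceMatrix,
    call_presence,
    compute_proportions,
)


class BiomePolygonSet:
    """Named, simple polygons in (MAT degC, MAP) climate space."""

    def __init__(self, polygons: dict[str, shapely.Geometry]):
        if not polygons:
            raise ValueError("empty biome polygon set")
        for name, poly in polygons.items():
            if not poly.is_valid:
                raise ValueError(f"biome polygon {name!r} is not simple/valid")
        self.polygons = dict(sorted(polygons.items()))

    @classmethod
    def from_geojson(cls, obj: dict) -> "BiomePolygonSet":
        return cls({f["properties"]["name"]: shapely_shape(f["geometry"]) for f in obj["features"]})


def default_biome_polygons() -> BiomePolygonSet:
    """The synthetic simplified Whittaker-style diagram shipped with the
    package (MAP axis in cm); see the fixture's embedded note."""
    with resources.files("lifecyclegeo.data").joinpath("whittaker_biomes_synthetic.geojson").open() as fh:
        return BiomePolygonSet.from_geojson(json.load(fh))


@dataclass
class BiomeAssignment:
    region: object
    biome: str
    method: str  # interior | plurality-circle | nearest


def assign_biome(
    point: tuple[float, float],
    polygons: BiomePolygonSet,
    r0: float = 0.5,
    area_tol: float = 1e-9,
    max_steps: int = 200,
) -> tuple[str, str]:
    """Biome of one (MAT, MAP) point; returns (biome name, method).

    The plurality circle grows in arithmetic steps r0, 2*r0, ... until one
    biome's intersected area strictly exceeds all others by ``area_tol``.
    A perfectly symmetric configuration that never resolves breaks the tie
    deterministically by (largest area, then name order).
    """
    pt = Point(point)
    inside = [n for n, poly in polygons.polygons.items() if poly.contains(pt)]
    if len(inside) == 1:
        return inside[0], "interior"

    touching = [n for n, poly in polygons.polygons.items() if poly.intersects(pt)]
    if not inside and not touching:
        dists = {n: poly.distance(pt) for n, poly in polygons.polygons.items()}
        best = min(dists, key=lambda n: (dists[n], n))
        return best, "nearest"

    # boundary or degenerate containment: enlarging-circle plurality
    first_ranked: list[tuple[str, float]] = []
    for step in range(1, max_steps + 1):
        circle = pt.buffer(step * r0, quad_segs=64)
        areas = {n: poly.intersection(circle).area for n, poly in polygons.polygons.items()}
        ranked = sorted(areas.items(), key=lambda kv: (-kv[1], kv[0]))
        if step == 1:
            first_ranked = ranked
        if ranked[0][1] > ranked[1][1] + area_tol:
            return ranked[0][0], "plurality-circle"
    # perfectly symmetric tie: decide among the locally adjacent biomes from
    # the smallest circle (largest area, then name), never a distant one
    return first_ranked[0][0], "plurality-circle"


def assign_biomes(
    region_climate: pd.DataFrame,
    polygons: BiomePolygonSet | None = None,
    mat_col: str = "bio1",
    map_col: str = "bio12",
    map_scale: float = 0.1,
    r0: float = 0.5,
) -> pd.DataFrame:
    """Assign every region to a biome from its (bio1, bio12) coordinates.

    ``map_scale`` converts the precipitation column into the polygon file's
    units (default mm -> cm, matching the shipped diagram). Returns a
    DataFrame indexed by region with columns biome and method.
    """
    polys = polygons if polygons is not None else default_biome_polygons()
    rows = []
    for region, rec in region_climate.iterrows():
        biome, method = assign_biome((rec[mat_col], rec[map_col] * map_scale), polys, r0=r0)
        rows.append({"region": region, "biome": biome, "method": method})
    return pd.DataFrame(rows).set_index("region")


def biome_presence(
    records: pd.DataFrame,
    assignments: pd.DataFrame,
    species_traits: pd.DataFrame,
    min_obs: int = PRESENCE_MIN_OBS,
    min_species: int = REGION_MIN_SPECIES,
) -> tuple[PresenceMatrix, pd.DataFrame]:
    """Pool observations to biome level and re-call presence and proportions.

    ``records`` must carry a ``region`` column; ``assignments`` maps region
    -> biome. Counts are pooled across a biome's member regions before the
    presence threshold applies, so the biome species list can exceed the
    union of its regions' lists.
    """
    biome_of = assignments["biome"]
    df = records[records["region"].isin(biome_of.index)].copy()
    df["region"] = df["region"].map(biome_of)
    matrix = call_presence(df, species_traits, min_obs=min_obs, min_species=min_species)
    props = compute_proportions(matrix)
    props.index.name = "biome"
    return matrix, props
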