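"""Synthetic worlds with known ground truth for pipeline validation.

The generator emits every input the analysis consumes — raw trait entries,
a synonym table, a crop list, GBIF-style occurrence points (with controlled
fractions of records violating each cleaning filter), an ecoregion map,
multi-year monthly climate cubes, a human-footprint grid and an ultrametric
phylogeny — together with the truth needed to verify the pipeline end to
end: each species' life cycle and each region's annual proportions.

The world is built on a rectangular pixel grid partitioned into
axis-aligned rectangular "ecoregions". Warm-quarter temperature increases
along grid rows and warm-quarter precipitation along columns, giving two
orthogonal climate gradients, plus i.i.d. year-to-year noise with
configurable ITV (temperature s.d.) and IPV (precipitation CV) targets.
Each species draws its annual/perennial identity from a Bernoulli whose
logit is linear in its home region's warm-quarter mean temperature and
log(warm-quarter precipitation + 1) — the same functional form the driver
models fit — so regression analyses have a known generating surface.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import box

from . import climate as climod
from .occurrences import RegionMap, write_gbif_tsv

#: occurrence filters the generator can inject violations of
DIRTY_FILTERS = (
    "missing_coords",
    "uncertainty",
    "event_year",
    "taxon_rank",
    "basis_of_record",
    "out_of_region",
)

_ANNUAL_TERMS = ("annual", "annual herb", "therophyte", "winter annual")
_PERENNIAL_HERB_TERMS = ("perennial", "perennial herb", "forb", "herb")
_WOODY_TERMS = ("tree", "shrub", "woody perennial")
_JUNK_TERMS = ("aquatic", "epiphyte", "2.4", "NO")


@dataclass
class SyntheticWorldConfig:
    """Knobs of the synthetic world; defaults define the study conditions.

    ``annual_logit_coefs`` is (intercept, slope per degC of warm-quarter
    temperature, slope per unit log(warm-quarter precipitation mm + 1)).
    The defaults put annual prevalence near 1% in cold-wet regions and near
    70% in hot-dry ones, bracketing the range observed across real
    ecoregions. ``dirty_fractions`` gives, per cleaning filter, the number
    of violating records injected as a fraction of the clean record count.
    """

    n_regions: int = 100
    grid_shape: tuple[int, int] = (20, 20)
    n_species: int = 1000
    n_years: int = 20
    annual_logit_coefs: tuple[float, float, float] = (0.25, 0.12, -0.9)
    dirty_fractions: dict[str, float] = field(default_factory=dict)
    obs_per_species_region: float = 12.0
    seed: int = 0

    # secondary structure
    extra_regions_mean: float = 1.5  # Poisson mean of extra home regions per species
    woody_fraction: float = 0.35  # of perennial species
    synonym_fraction: float = 0.10  # of trait entries filed under a synonym
    conflict_fraction: float = 0.02  # of species given contradictory life-cycle terms
    crop_fraction: float = 0.02  # of species placed on the crop list
    itv_sd: float = 0.6  # degC, between-year s.d. of yearly mean temperature
    ipv_cv: float = 0.15  # CV of yearly precipitation totals
    t_warm_range: tuple[float, float] = (0.0, 30.0)
    p_warm_range: tuple[float, float] = (10.0, 400.0)  # mm over the warm quarter
    seasonal_amp: float = 8.0  # degC half-range of the within-year temperature cycle
    families: tuple[str, ...] = ("Asteraceae", "Brassicaceae", "Fabaceae", "Poaceae")
    lon0: float = 2.0
    lat0: float = 2.0
    pixel_deg: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_species", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape entries must be >= 1")
        for key, frac in self.dirty_fractions.items():
            if key not in DIRTY_FILTERS:
                raise ValueError(f"unknown dirty filter {key!r}; known: {DIRTY_FILTERS}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("dirty fractions must lie in [0, 1]")
        if self.n_species * (1.0 + self.extra_regions_mean) / self.n_regions < 1.0:
            raise ValueError("expected species per region < 1; enlarge n_species")


@dataclass
class SyntheticWorld:
    """A generated world plus its ground truth (see module docstring)."""

    config: SyntheticWorldConfig
    trait_entries: pd.DataFrame  # raw_name, raw_term, source
    synonym_table: pd.DataFrame  # raw_name -> accepted_name (incl. identities)
    crop_list: set[str]
    occurrences: pd.DataFrame  # pipeline occurrence columns, dirty rows included
    region_map: RegionMap
    region_id_grid: np.ndarray  # (rows, cols) region id per climate pixel
    temp_cube: np.ndarray  # (n_years, 12, rows, cols) degC
    prec_cube: np.ndarray  # (n_years, 12, rows, cols) mm
    footprint_grid: np.ndarray  # (rows, cols), dimensionless
    phylogeny: dendropy.Tree  # ultrametric, tips = accepted species names
    truth_species: pd.DataFrame  # life_cycle, growth_form, family, trait_usable, home_region
    truth_regions: pd.DataFrame  # counts, proportions, sufficiency, generating climate
    dirty_ledger: dict[str, int]  # injected violation count per filter


def _block_layout(n_regions: int, grid_shape: tuple[int, int]) -> tuple[int, int]:
    """Factor n_regions into a (block_rows, block_cols) tiling of the grid."""
    rows, cols = grid_shape
    candidates = [
        (r, n_regions // r)
        for r in range(1, n_regions + 1)
        if n_regions % r == 0 and rows % r == 0 and cols % (n_regions // r) == 0
    ]
    if not candidates:
        raise ValueError(f"cannot tile grid {grid_shape} with {n_regions} rectangular regions")
    target = rows / cols
    return min(candidates, key=lambda rc: (abs(rc[0] / rc[1] - target), rc[0]))


def _seasonal_weights(amp: float) -> tuple[np.ndarray, np.ndarray]:
    """Monthly temperature offsets (peak in July) and precipitation weights
    normalized so the July-centred quarter receives weight 1."""
    m = np.arange(12)
    phase = 2.0 * np.pi * (m - 6) / 12.0
    t_offset = -amp * (1.0 - np.cos(phase))
    w = (1.0 + np.cos(phase)) ** 2
    w = w / w[5:8].sum()
    return t_offset, w


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build a complete synthetic world (deterministic under a fixed seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape

    # --- regions: axis-aligned blocks of the pixel grid -------------------
    brows, bcols = _block_layout(cfg.n_regions, cfg.grid_shape)
    bh, bw = rows // brows, cols // bcols
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    region_id_grid = (ii // bh) * bcols + (jj // bw)

    def pix_lon(j: np.ndarray) -> np.ndarray:
        return cfg.lon0 + (np.asarray(j) + 0.5) * cfg.pixel_deg

    def pix_lat(i: np.ndarray) -> np.ndarray:
        return cfg.lat0 + (np.asarray(i) + 0.5) * cfg.pixel_deg

    polygons = {}
    for rid in range(cfg.n_regions):
        br, bc = rid // bcols, rid % bcols
        polygons[rid] = box(
            cfg.lon0 + bc * bw * cfg.pixel_deg,
            cfg.lat0 + br * bh * cfg.pixel_deg,
            cfg.lon0 + (bc + 1) * bw * cfg.pixel_deg,
            cfg.lat0 + (br + 1) * bh * cfg.pixel_deg,
        )
    region_map = RegionMap(polygons)

    # --- climate cubes -----------------------------------------------------
    t_lo, t_hi = cfg.t_warm_range
    p_lo, p_hi = cfg.p_warm_range
    t_warm = t_lo + (t_hi - t_lo) * (ii / max(rows - 1, 1))
    # geometric spacing spreads regions evenly on the log-precip axis
    p_warm = p_lo * (p_hi / p_lo) ** (jj / max(cols - 1, 1))
    t_offset, p_weight = _seasonal_weights(cfg.seasonal_amp)
    temp_clim = t_warm[None] + t_offset[:, None, None]  # (12, rows, cols)
    prec_clim = p_warm[None] * p_weight[:, None, None]

    year_t = rng.normal(0.0, cfg.itv_sd, size=(cfg.n_years, rows, cols))
    year_p = np.clip(rng.normal(1.0, cfg.ipv_cv, size=(cfg.n_years, rows, cols)), 0.05, None)
    temp_cube = temp_clim[None] + year_t[:, None]
    prec_cube = prec_clim[None] * year_p[:, None]

    footprint_grid = np.clip(
        25.0 * (ii + jj) / max(rows + cols - 2, 1) + rng.normal(0.0, 2.0, size=(rows, cols)),
        0.0,
        None,
    )

    # generating climate at the regional grain: BIOCLIM of the climatology,
    # median over region pixels (the same grain every model uses)
    bio = climod.quarterly_bioclim(climod.climatology(temp_cube), climod.climatology(prec_cube))
    region_bio10 = climod.aggregate_region(bio["bio10"], region_id_grid)
    region_bio18 = climod.aggregate_region(bio["bio18"], region_id_grid)

    # --- species ------------------------------------------------------------
    names = np.array([f"Synthea specie{i:05d}" for i in range(cfg.n_species)])
    home = rng.integers(0, cfg.n_regions, size=cfg.n_species)
    n_extra = rng.poisson(cfg.extra_regions_mean, size=cfg.n_species)
    a, bT, bP = cfg.annual_logit_coefs
    logit = a + bT * region_bio10.loc[home].to_numpy() + bP * np.log(region_bio18.loc[home].to_numpy() + 1.0)
    p_annual = 1.0 / (1.0 + np.exp(-logit))
    is_annual = rng.random(cfg.n_species) < p_annual
    is_woody = (~is_annual) & (rng.random(cfg.n_species) < cfg.woody_fraction)
    family = rng.choice(np.array(cfg.families), size=cfg.n_species)

    is_conflict = rng.random(cfg.n_species) < cfg.conflict_fraction
    is_crop = (~is_conflict) & (rng.random(cfg.n_species) < cfg.crop_fraction)
    trait_usable = ~(is_conflict | is_crop)
    crop_list = set(names[is_crop])

    truth_species = pd.DataFrame(
        {
            "species": names,
            "life_cycle": np.where(is_annual, "annual", "perennial"),
            "growth_form": np.where(is_annual | ~is_woody, "herbaceous", "woody"),
            "family": family,
            "home_region": home,
            "p_annual_model": p_annual,
            "trait_usable": trait_usable,
        }
    ).set_index("species")

    # --- trait entries and synonym table -----------------------------------
    entry_rows: list[tuple[str, str, str]] = []
    synonym_rows: list[tuple[str, str]] = [(n, n) for n in names]
    for k, name in enumerate(names):
        # every species gets one life-cycle term and one growth-form-bearing
        # term so both consensus axes are determinable from clean entries
        if is_woody[k]:
            pool = _WOODY_TERMS
            terms = [pool[0]]
        elif is_annual[k]:
            pool = _ANNUAL_TERMS
            terms = [pool[0], "herb"]
        else:
            pool = _PERENNIAL_HERB_TERMS
            terms = [pool[0], "herb"]
        terms += list(rng.choice(np.array(pool), size=rng.poisson(1.0)))
        if rng.random() < 0.1:
            terms.append(str(rng.choice(np.array(_JUNK_TERMS))))
        if is_conflict[k]:
            terms.append(_PERENNIAL_HERB_TERMS[0] if is_annual[k] else _ANNUAL_TERMS[0])
        raw_name = name
        if rng.random() < cfg.synonym_fraction:
            raw_name = name + "um"
            synonym_rows.append((raw_name, name))
        for t in terms:
            entry_rows.append((raw_name, t, f"db{rng.integers(1, 12)}"))
    trait_entries = pd.DataFrame(entry_rows, columns=["raw_name", "raw_term", "source"])
    synonym_table = pd.DataFrame(synonym_rows, columns=["raw_name", "accepted_name"])

    # --- clean occurrences ---------------------------------------------------
    sp_idx: list[int] = []
    sp_region: list[int] = []
    for k in range(cfg.n_species):
        regs = {int(home[k])}
        if n_extra[k]:
            regs.update(int(r) for r in rng.integers(0, cfg.n_regions, size=n_extra[k]))
        for r in sorted(regs):
            sp_idx.append(k)
            sp_region.append(r)
    counts = rng.poisson(cfg.obs_per_species_region, size=len(sp_idx))
    rec_sp = np.repeat(np.array(sp_idx), counts)
    rec_region = np.repeat(np.array(sp_region), counts)
    n_rec = len(rec_sp)

    br_of = rec_region // bcols
    bc_of = rec_region % bcols
    lon = cfg.lon0 + (bc_of * bw + rng.random(n_rec) * bw) * cfg.pixel_deg
    lat = cfg.lat0 + (br_of * bh + rng.random(n_rec) * bh) * cfg.pixel_deg
    uncertainty = np.where(rng.random(n_rec) < 0.2, np.nan, rng.uniform(10.0, 50_000.0, n_rec))
    clean = pd.DataFrame(
        {
            "species": names[rec_sp],
            "lon": lon,
            "lat": lat,
            "coordinate_uncertainty": uncertainty,
            "basis_of_record": rng.choice(np.array(["HUMAN_OBSERVATION", "PRESERVED_SPECIMEN"]), n_rec),
            "event_year": rng.integers(1960, 2021, size=n_rec).astype(float),
            "taxon_rank": "SPECIES",
        }
    )

    # --- ground-truth regional proportions (from clean data only) ----------
    truth_counts = (
        pd.DataFrame({"species": clean["species"], "region": rec_region})
        .groupby(["region", "species"])
        .size()
    )
    present = truth_counts[truth_counts >= 5].reset_index()[["region", "species"]]
    present = present.join(truth_species[["life_cycle", "growth_form", "trait_usable"]], on="species")
    present = present[present["trait_usable"]]
    herbs = present[present["growth_form"] == "herbaceous"]
    truth_regions = pd.DataFrame(
        {
            "n_species": present.groupby("region")["species"].nunique(),
            "n_annual": present[present["life_cycle"] == "annual"].groupby("region")["species"].nunique(),
            "n_herb_species": herbs.groupby("region")["species"].nunique(),
            "n_annual_herb": herbs[herbs["life_cycle"] == "annual"].groupby("region")["species"].nunique(),
        }
    ).reindex(range(cfg.n_regions), fill_value=0).fillna(0).astype(int)
    truth_regions.index.name = "region"
    truth_regions["sufficient_all"] = truth_regions["n_species"] >= 10
    truth_regions["sufficient_herb"] = truth_regions["n_herb_species"] >= 10
    with np.errstate(invalid="ignore", divide="ignore"):
        truth_regions["p_annual"] = np.where(
            truth_regions["sufficient_all"], truth_regions["n_annual"] / truth_regions["n_species"], np.nan
        )
        truth_regions["p_annual_herb"] = np.where(
            truth_regions["sufficient_herb"],
            truth_regions["n_annual_herb"] / truth_regions["n_herb_species"],
            np.nan,
        )
    truth_regions["bio10"] = region_bio10
    truth_regions["bio18"] = region_bio18

    # --- dirty records -------------------------------------------------------
    dirty_ledger = {name: 0 for name in DIRTY_FILTERS}
    dirty_frames = []
    for name in DIRTY_FILTERS:
        frac = cfg.dirty_fractions.get(name, 0.0)
        n_dirty = int(rng.binomial(n_rec, frac)) if frac > 0 else 0
        dirty_ledger[name] = n_dirty
        if n_dirty == 0:
            continue
        d = clean.iloc[rng.integers(0, n_rec, size=n_dirty)].copy().reset_index(drop=True)
        if name == "missing_coords":
            d["lon"] = np.nan
            d["lat"] = np.nan
        elif name == "uncertainty":
            d["coordinate_uncertainty"] = rng.uniform(100_001.0, 500_000.0, n_dirty)
        elif name == "event_year":
            d["event_year"] = rng.integers(1900, 1946, size=n_dirty).astype(float)
        elif name == "taxon_rank":
            d["taxon_rank"] = "GENUS"
        elif name == "basis_of_record":
            d["basis_of_record"] = rng.choice(np.array(["LITERATURE", "LIVING_SPECIMEN"]), n_dirty)
        elif name == "out_of_region":
            d["lon"] = cfg.lon0 - rng.uniform(1.0, 5.0, n_dirty)
        dirty_frames.append(d)
    occurrences = pd.concat([clean, *dirty_frames], ignore_index=True)
    occurrences = occurrences.iloc[rng.permutation(len(occurrences))].reset_index(drop=True)

    # --- phylogeny -----------------------------------------------------------
    phylogeny = _simulate_tree(list(names), seed=int(rng.integers(0, 2**31 - 1)))

    return SyntheticWorld(
        config=cfg,
        trait_entries=trait_entries,
        synonym_table=synonym_table,
        crop_list=crop_list,
        occurrences=occurrences,
        region_map=region_map,
        region_id_grid=region_id_grid,
        temp_cube=temp_cube,
        prec_cube=prec_cube,
        footprint_grid=footprint_grid,
        phylogeny=phylogeny,
        truth_species=truth_species,
        truth_regions=truth_regions,
        dirty_ledger=dirty_ledger,
    )


def _simulate_tree(names: list[str], seed: int) -> dendropy.Tree:
    """Pure-birth ultrametric tree over the given tip names, depth scaled to 1."""
    taxa = dendropy.TaxonNamespace(names)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(names),
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    # the simulation stops exactly at the n-th speciation, leaving zero-length
    # terminal branches; extend every tip edge equally (stays ultrametric and
    # keeps the Brownian covariance positive definite)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.1 * depth
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def generate_brownian_traits(
    tree: dendropy.Tree,
    sigma2: float,
    beta: float,
    seed: int,
    states: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate a binary state and a state-shifted Brownian trait on a tree.

    The continuous trait of tip i is ``beta * state_i + e_i`` where the
    deviates e follow Brownian motion along branches: cov(e_i, e_j) =
    sigma2 * (shared root-to-tip path length). States may be supplied per
    tip (0/1 Series indexed by taxon label); otherwise they come from
    thresholding an independent unit-rate Brownian trait at zero, which
    yields phylogenetically clumped states as real life cycles are.

    Returns a DataFrame indexed by taxon label with columns state, trait.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)

    def simulate_bm(rate: float) -> dict[str, float]:
        value = {tree.seed_node: 0.0}
        out = {}
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                el = node.edge.length or 0.0
                value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(rate * el))
            if node.is_leaf():
                out[node.taxon.label] = value[node]
        return out

    deviates = simulate_bm(sigma2)
    labels = list(deviates.keys())
    if states is None:
        z = simulate_bm(1.0)
        state = {t: int(z[t] > 0.0) for t in labels}
    else:
        state = {t: int(states[t]) for t in labels}
    df = pd.DataFrame(
        {"state": [state[t] for t in labels], "trait": [beta * state[t] + deviates[t] for t in labels]},
        index=pd.Index(labels, name="species"),
    )
    return df


def simulate_region_table(
    n_regions: int = 200,
    coefs: tuple[float, float, float] = (0.25, 0.12, -0.9),
    n_herb_mean: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-region predictor/response table for model studies.

    Each region gets a 12-month climate whose yearly mean, seasonal
    amplitude, precipitation total and summer-vs-winter rainfall share are
    drawn independently, so the quarterly BIOCLIM variables are correlated
    but not collinear (in particular, rainfall may peak in the warm or the
    cold season, decoupling bio18 from bio16). The true annual-herb
    proportion follows ``logit p = a + bT*bio10 + bP*log(bio18+1)`` with
    ``coefs = (a, bT, bP)``, and the observed proportion adds binomial
    sampling noise from a finite herb-species pool (mean ``n_herb_mean``).

    Returns a DataFrame indexed by region with the ten BIOCLIM columns,
    n_herb_species, n_annual_herb, p_annual_herb and the latent p_true.
    """
    rng = np.random.default_rng(seed)
    m = np.arange(12)
    phase = 2.0 * np.pi * (m - 6) / 12.0
    t_mean = rng.uniform(-5.0, 25.0, n_regions)
    t_amp = rng.uniform(2.0, 15.0, n_regions)
    p_total = np.exp(rng.uniform(np.log(100.0), np.log(2500.0), n_regions))
    summer_share = rng.uniform(0.05, 0.95, n_regions)
    summer_w = (1.0 + np.cos(phase)) ** 2
    summer_w /= summer_w.sum()
    winter_w = (1.0 - np.cos(phase)) ** 2
    winter_w /= winter_w.sum()

    temp = t_mean[None, :] + t_amp[None, :] * np.cos(phase)[:, None]
    prec = p_total[None, :] * (
        summer_share[None, :] * summer_w[:, None] + (1 - summer_share[None, :]) * winter_w[:, None]
    )
    bio = climod.quarterly_bioclim(temp, prec)
    table = pd.DataFrame(bio, index=pd.RangeIndex(n_regions, name="region"))

    a, bT, bP = coefs
    logit = a + bT * table["bio10"] + bP * np.log(table["bio18"] + 1.0)
    p_true = 1.0 / (1.0 + np.exp(-logit))
    n_herb = rng.poisson(n_herb_mean, n_regions) + 10
    x = rng.binomial(n_herb, p_true)
    table["n_herb_species"] = n_herb
    table["n_annual_herb"] = x
    table["p_annual_herb"] = x / n_herb
    table["p_true"] = p_true
    return table


# --- on-disk writers --------------------------------------------------------

def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize a world to plain-text files.

    Layout: trait_entries.csv, synonyms.csv, crops.csv, occurrences.tsv
    (GBIF-style headers), regions.geojson, region_grid.csv (region id per
    pixel), climate.csv (long format: year, month, row, col, temperature,
    precipitation), footprint.csv and tree.newick.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.trait_entries.to_csv(out / "trait_entries.csv", index=False)
    world.synonym_table.to_csv(out / "synonyms.csv", index=False)
    pd.DataFrame({"species": sorted(world.crop_list)}).to_csv(out / "crops.csv", index=False)
    write_gbif_tsv(world.occurrences, out / "occurrences.tsv")
    import json

    (out / "regions.geojson").write_text(json.dumps(world.region_map.to_geojson()))
    pd.DataFrame(world.region_id_grid).to_csv(out / "region_grid.csv", index=False, header=False)
    ny, _, rows, cols = world.temp_cube.shape
    yy, mm, ri, ci = np.meshgrid(
        np.arange(ny), np.arange(12), np.arange(rows), np.arange(cols), indexing="ij"
    )
    pd.DataFrame(
        {
            "year": yy.ravel(),
            "month": mm.ravel(),
            "row": ri.ravel(),
            "col": ci.ravel(),
            "temperature": world.temp_cube.ravel(),
            "precipitation": world.prec_cube.ravel(),
        }
    ).to_csv(out / "climate.csv", index=False)
    pd.DataFrame(world.footprint_grid).to_csv(out / "footprint.csv", index=False, header=False)
    world.phylogeny.write(path=str(out / "tree.newick"), schema="newick")


def read_climate_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the long-format climate CSV back into (temp_cube, prec_cube)."""
    df = pd.read_csv(path)
    ny = df["year"].max() + 1
    rows = df["row"].max() + 1
    cols = df["col"].max() + 1
    df = df.sort_values(["year", "month", "row", "col"])
    shape = (ny, 12, rows, cols)
    return (
        df["temperature"].to_numpy().reshape(shape),
        df["precipitation"].to_numpy().reshape(shape),
    )
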