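# Methods

This note documents the statistical procedures implemented in
`lifecyclegeo`, the parameter defaults and their rationale, the numerical
choices that affect results, and the scope and limitations of the
synthetic-world generator used for validation.

## 1. Trait consensus

Raw database entries (`raw_name`, `raw_term`, `source`) are processed in
three stages.

**Name resolution.** Names are matched exactly (after whitespace
normalization) against a synonym table mapping raw names to accepted
species names. Unmatched names are dropped and counted; no fuzzy matching
is attempted, because misattributing a trait record to the wrong species
is worse than losing the record.

**Term interpretation.** Each raw term is looked up (case-insensitively)
in a lexicon mapping it to a life-cycle vote (`annual`, `perennial`, or
none) and a growth-form vote (`herbaceous`, `woody`, none, or `conflict`
for terms such as "shrub/herb" that cannot be split). Numeric terms (for
example plant heights) carry no vote. **Biennial** terms vote herbaceous
but carry *no* life-cycle vote: a biennial is neither a within-one-season
annual nor a polycarpic perennial, and letting it vote either way would
contaminate both classes.

**Consensus.** Per species and axis, the votes must be unanimous;
any contradiction excludes the species from that axis (`conflict`).
Two constraints apply after voting: a woody species is forced to
perennial (woody annuals are botanically negligible and almost always
data errors), and species on a crop list are excluded entirely because
cultivation decouples their range from climate. A species is *usable*
when it has an uncontested life-cycle call. The partition report
(kept / excluded_conflict / excluded_crop / excluded_no_lifecycle) always
sums to the number of resolved species, and the pipeline asserts this.

## 2. Occurrence cleaning

Records are screened by six filters, applied in a fixed order with each
removal attributed to the *first* failing filter so that the removal
ledger sums exactly to the number of dropped records:

1. missing coordinates;
2. coordinate validity: out of range (|lat| > 90, |lon| > 180), the
   (0, 0) point, and longitude exactly equal to latitude (two common
   database-entry artefacts);
3. coordinate uncertainty > 100 000 m (`MAX_UNCERTAINTY_M`) — coarser
   records cannot be trusted to a ~100-km ecoregion (missing uncertainty
   is tolerated);
4. basis of record in {LITERATURE, LIVING_SPECIMEN} — not verifiable
   wild occurrences;
5. collection year before 1946 (`MIN_EVENT_YEAR`) — older records
   predate the climate normals and often carry georeferencing guessed
   long after collection (records with no year are dropped by default;
   `drop_null_year=False` retains them);
6. taxon rank other than species.

**Presence and sufficiency.** A species is present in a region when it
has at least `PRESENCE_MIN_OBS = 5` cleaned records there — single
records are too often misidentifications or vagrants. A region enters the
analysis only with at least `REGION_MIN_SPECIES = 10` present species;
a proportion estimated from fewer species is dominated by sampling noise.
The herbaceous analysis **re-evaluates sufficiency on herbaceous species
only**: a region with 12 present species of which 6 are herbs yields an
overall proportion but no herb proportion. Insufficient regions get NaN,
never zero.

Proportions are reported on two denominators: `p_annual` among all
usable species, and `p_annual_herb` among herbaceous species only. The
herb-only figure is the primary response, since the annual/perennial
contrast within herbs is not confounded by the (always perennial) woody
flora.

## 3. Climate features

**Quarterly BIOCLIM variables.** From 12 monthly values per pixel, all 12
wrapped 3-month windows are formed (window *s* covers months *s*,
*s*+1, *s*+2 modulo 12). Window mean temperature and precipitation sum
give: bio1 (annual mean temperature), bio8/bio9 (mean temperature of the
wettest/driest quarter), bio10/bio11 (warmest/coldest quarter), bio12
(annual precipitation), bio16/bio17 (precipitation of the wettest/driest
quarter), bio18/bio19 (warmest/coldest quarter). Ties between windows are
broken by the **earliest starting month** (numpy `argmax` semantics),
deterministically. Masked (NaN) pixels propagate to NaN outputs.

**Interannual variability.** Per pixel, IPV is the coefficient of
variation of *yearly precipitation totals* and ITV the standard deviation
of *yearly mean temperatures*, both with sample normalization
(`ddof=1`). ITV is an s.d., not a CV, because temperature in degC has an
arbitrary zero.

**Aggregation.** Every per-pixel quantity is computed first and then
reduced to the **regional median** (NaN pixels ignored; id −1 marks
pixels outside all regions). Median-of-pixels is robust to the skewed
within-region distributions of precipitation; computing BIOCLIM on
region-mean climates instead would mix the seasonal cycles of different
pixels and is deliberately avoided.

## 4. Biome assignment

Each region is a point in the plane of mean annual temperature (degC)
and annual precipitation (cm; `map_scale=0.1` converts from mm). The
shipped diagram (`data/whittaker_biomes_synthetic.geojson`) is a
**synthetic, simplified, rectangle-based** Whittaker-style tessellation
of nine biomes — adequate for exercising the assignment logic, and
clearly labelled as such in the file; substitute a digitized diagram via
`BiomePolygonSet.from_geojson` for real analyses. Assignment has three
cases:

* **interior** — the point is strictly inside one polygon;
* **plurality-circle** — the point lies on a boundary; a circle of radius
  r0, 2·r0, … (default r0 = 0.5 in axis units) grows until one biome's
  intersected area strictly exceeds all others (tolerance 1e-9). A
  perfectly symmetric tie that never resolves falls back to the ranking
  at the smallest circle (largest area, then name), which confines the
  choice to locally adjacent biomes;
* **nearest** — the point is outside the whole diagram and takes the
  closest polygon by Euclidean distance.

Biome-level presence **pools raw observation counts across the biome's
member regions before the 5-record rule**, so a species with 3 + 2
records in two regions of one biome is absent from both regions but
present in the biome. Proportions are then recomputed at biome level
with the same sufficiency rule.

## 5. Driver models

**Model family.** Ordinary least squares of a regional proportion on
climate terms. The term grammar supports raw columns, `log(col+1)`
transforms (precipitation spans orders of magnitude and includes zeros),
and `a:b` interactions.

**AICc.** AICc = AIC + 2k(k+1)/(n−k−1) with **k = number of mean
parameters + 1** for the estimated residual variance — the convention
under which Gaussian AICc model ranking is consistent. The test suite
cross-checks the value against the closed form from the residual sum of
squares.

**Exhaustive quarterly search.** 34 candidates: every pair of one
quarterly temperature (bio8–bio11) with one log quarterly precipitation
(log(bio16+1)…log(bio19+1)) — 16 models — plus the same 16 with yearly
terms substituted in turn, and two yearly baselines including
bio1 + log(bio12+1) and its interaction form. Candidates are ranked by
AICc; the ranking table reports R², AICc and ΔAICc.

**Nested extensions.** A base model and its extension by ipv, itv or the
human-footprint index are compared by ΔAICc **on the identical case
set** (rows complete for the extended model), since AICc values on
different data are incomparable.

**Alternative response scales.** (a) OLS on the smoothed empirical logit
log[(x+0.5)/(n−x+0.5)] — the +0.5 (Haldane–Anscombe) smoothing keeps 0
and n finite; (b) a Poisson GLM of the annual count with offset
log(total), giving a per-species rate interpretation; regions with a
zero total are excluded. These probe whether conclusions depend on the
linear-probability approximation.

**Spatial structure.** Distance-based Moran eigenvector maps (dbMEM):
great-circle (haversine) distances between region centroids are
truncated at the longest edge of their minimum spanning tree (the
smallest threshold keeping the graph connected); larger distances are
replaced by 4× the threshold (the classical dbMEM recipe); the squared
distance matrix is Gower double-centered and eigendecomposed; vectors are
taken in decreasing |eigenvalue| order until ≥ 80 % of total |eigenvalue|
is covered (`variance_target=0.8`). Moran's I uses binary
within-threshold weights. Coincident centroids either raise an error or
are jittered on request. Adding the MEM basis as covariates absorbs
broad-scale spatial autocorrelation from the residuals.

**Phylogenetic regression.** pGLS of a species-level climate response on
the 0/1 annual indicator under Brownian motion: V holds shared
root-to-tip path lengths, estimation is by Cholesky-whitened least
squares, branch lengths are taken as given (no Pagel transforms). A
companion OLS on the same data quantifies how much relatedness matters.
Each climate variable is analysed as a **separate response**; a
multivariate phylogenetic model is out of scope.

**Sampling-bias diagnostics.** Regressions of each regional response on
log10 total record count (and richness) flag depth-of-sampling artefacts.

## 6. Projection

A fitted model is evaluated on current and future regional climate
tables. Predictions are linear and may leave [0, 1]; both raw and
clipped values are reported, and **delta = future − current is computed
on the raw scale**, so the increase/decrease verdict is unaffected by
clipping. Regions missing from either table or with missing climate are
omitted. `increase_fraction` is the share of projected regions with
delta > 0.

## 7. Synthetic-world generator

`generate_world` builds, from one integer seed: a rectangular grid of
pixels tiled into block regions; orthogonal temperature and
precipitation gradients with a sinusoidal seasonal cycle (half-range
`seasonal_amp = 8` degC) and multi-year noise (additive N(0, itv_sd) on
yearly temperature, multiplicative clipped N(1, ipv_cv) on yearly
precipitation); a human-footprint gradient; species whose probability of
being annual follows logit p = a + b_T·bio10 + b_P·log(bio18+1) with
defaults (0.25, 0.12, −0.9), bracketing annual prevalences from ~1 % to
~70 %; trait entries routed through synonyms with injected conflicts and
crops; clean occurrence records with Poisson counts per species × region;
dirty records injected per filter with an **exact ledger**; and a
pure-birth ultrametric phylogeny (tip edges extended by 10 % of tree
depth to keep the Brownian covariance positive definite, then rescaled
to unit depth) with Brownian trait simulation and threshold-derived
binary states.

Ground truth is defined from the *realized* clean record counts (≥ 5
rule among trait-usable species), so the pipeline must recover it
exactly — and the acceptance tests verify that it does, region by
region.

**Limitations.**

* The seasonal cycle has a single phase and amplitude everywhere, so
  across regions all quarterly temperature variables are perfectly
  correlated (each is the annual mean plus a constant), and similarly
  all quarterly precipitation variables are proportional. Quarterly
  model selection on a generated *world* therefore produces near-ties by
  construction; `scripts/acceptance.py` reports the generating pair's
  ΔAICc (tiny) rather than pretending a unique winner exists. Selection
  *power* is instead validated with `simulate_region_table`, which
  randomizes each region's seasonal amplitude and summer/winter
  precipitation share so the quarterly variables decouple; the
  acceptance test requires the generating (bio10, log(bio18+1)) pair to
  win in ≥ 95 of 100 replicates.
* Regions are axis-aligned rectangles with no coastline, elevation or
  dispersal structure; occurrence locations are uniform within the home
  region.
* Species states are independent Bernoulli draws given climate — the
  phylogeny used for pGLS validation is generated separately with its
  own Brownian traits rather than being coupled to the world's species.
* Dirty records are injected as *extra* rows, so cleaning restores the
  clean set exactly; real data have no such guarantee.

## 8. Numerical choices

* All variances/s.d./CV use sample normalization (`ddof=1`).
* BIOCLIM window ties break to the earliest starting month; presence and
  region boundaries break ties to the lowest region id; a point on a
  shared region boundary belongs to the lowest-id region (`covered_by`
  semantics, so boundary points are never lost).
* Grid cells for record thinning use a cylindrical equal-area projection
  (x = R·lon_rad, y = R·sin lat), giving exactly equal-area half-open
  cells of `cell_km = 100` km nominal size without external projection
  libraries.
* Rank-deficient design matrices raise an error naming the collinear
  column rather than silently dropping terms.
* Random number use is everywhere through `numpy.random.default_rng`
  with explicit seeds; derived seeds are drawn below 2^31.
* Model fits drop rows with missing values listwise per model; nested
  comparisons re-restrict to the extended model's case set first.
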