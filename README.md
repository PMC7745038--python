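# divgrid

Grid-based analysis of biodiversity hotspots from species occurrence
records: where are richness, endemism and threatened-species peaks, do
those different kinds of hotspot coincide, how much of the apparent
pattern is a sampling artefact, and where should future surveys go?

The package is aimed at biodiversity informaticians working with
presence-only occurrence databases (museum records, literature records,
citizen-science exports) for a country or region, of the kind assembled
for national conservation assessments of tetrapods. It implements the
complete analysis as a tested library plus a thin CLI, together with a
synthetic occurrence generator with known ground truth so that every
stage can be verified without access to any particular database.

## What it computes

Records (species, class group, planar x/y in metres, year, IUCN category
at the global and national level) are deduplicated — one record per
(species, coordinates, year) — and assigned to half-open square grid
cells (12.5, 25 and 50 km are the standard resolutions) clipped to a
country polygon. Per cell *i* it then computes:

- **Sampling effort** — number of records — and **species richness**
  SR_i, the number of distinct species.
- **Weighted endemism** (range-size-weighted richness)
  `E_i = Σ_j q_ij`, where `q_ij = 1 / (number of cells occupied by
  species j)` if *j* occurs in cell *i*, else 0. Each species carries one
  unit of endemism mass spread over its occupied cells, so
  `Σ_i E_i` equals the number of recorded species exactly.
- **Threatened species** number TSN_i and proportion
  `TSP_i = (CR + EN + VU) / N_i`, with N_i the cell's species count, at
  the global or national Red List level (mammals carry no national
  assessment and are refused at that level, as is the combined set).
- **Hotspots** as the top *d*% of non-empty cells on any metric, and the
  **congruence** of two or more hotspot maps as
  `100·|∩ selections| / |∪ selections|`, swept over d = 0.5…100% in
  half-percent steps; plus the share of hotspot cells at least partially
  covered by a protected-area polygon.
- **Autocorrelation-corrected correlations** between per-cell variables:
  the Pearson r with a modified t-test on `M̂ − 2` degrees of freedom,
  where the effective sample size M̂ comes from Moran-type correlograms
  of both variables (13 equal-width distance classes by default).
- **Coverage-standardised richness**: each cell's 1-km sub-grid yields
  incidence frequencies (T units, counts Y_j, singletons Q1, doubletons
  Q2); richness (Hill number q = 0) is interpolated/extrapolated and
  compared across cells at the common coverage levels C_max (minimum) and
  C_5% (5th percentile) of all cells extrapolated to double their size.
  Unreliable cells (S_obs < 6, or T < 6, or all species singletons) are
  excluded.
- **Survey completeness**: the exact species-accumulation curve per cell,
  the mean slope of its final 10%, and a five-level sampling-priority
  class (Null ≤ 0.05 < Low ≤ 0.25 < Medium ≤ 1; High = too few records
  for a curve; Very High = no records).

## Worked example

```python
from divgrid import (bias_scenario, generate, deduplicate, build_grid,
                     assign, cell_metric_table, select_hotspots, congruence)

sim = generate(bias_scenario("city", seed=7, n_records=3000,
                             n_species={"Amphibia": 12, "Reptilia": 15,
                                        "Aves": 45, "Mammalia": 18},
                             country_km=(200.0, 150.0)))
occ, n_dup = deduplicate(sim.occurrences)
grid = build_grid(sim.country, 25_000, crs_tag=occ.crs_tag)
table = cell_metric_table(occ, grid)
print(len(occ), "records,", table["E"].sum(), "species of endemism mass")

nonempty = table[table["effort"] > 0]
sels = [select_hotspots(nonempty[m].astype(float).fillna(0), 10.0, m)
        for m in ("SR", "E", "TSN_g")]
print("hotspot congruence at d=10%:", round(congruence(sels), 1), "%")
```

prints

```
3000 records, 88.0 species of endemism mass
hotspot congruence at d=10%: 10.0 %
```

All 3,000 simulated records are unique here; the summed weighted
endemism equals the 88 recorded species exactly (the conservation
property above); and only a tenth of the cells that are top-10% hotspots
for richness, endemism or threatened-species number are hotspots for all
three at once — richness peaks where sampling effort concentrates, while
the other metrics peak elsewhere.

The same stages are available from the shell:

```sh
divgrid simulate --preset city --seed 42 --out data/
divgrid metrics --occurrences data/occurrences.csv --country data/country.geojson \
    --cell-size 25000 --out metrics.csv
divgrid rarefy --occurrences data/occurrences.csv --country data/country.geojson \
    --out rarefied.csv
divgrid run-all --occurrences data/occurrences.csv --country data/country.geojson \
    --pas data/pas.geojson --out report/
```

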