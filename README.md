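# rapoport

Tools for testing **latitudinal gradients in species range size**
(Rapoport's rule) in gridded faunas, written for macroecologists who work
from occurrence records, a phylogeny, and gridded environmental layers.
The package covers the full path from raw point records to a
null-model-tested answer:

1. **Occurrence cleaning** — duplicate removal, one-record-per-cell grid
   thinning, and quantile-based spatial outlier removal (a record is
   dropped when its mean distance to conspecifics exceeds
   Q75 + 2·IQR of the per-record mean distances).
2. **Range polygons** — convex hulls or *dynamic alpha hulls*: the alpha
   parameter (a Delaunay circumradius bound, km) grows geometrically
   until the shape contains every record and is a single connected
   polygon; both methods take a Minkowski buffer (default 50 km) and
   report area in km².
3. **Equal-area gridding** — a spherical Albers equal-area projection and
   a 50 × 50 km lattice turn the polygons into a binary site × species
   presence–absence matrix (PAM), from which come each species' range
   size `A`, log range size `ln A`, latitudinal midpoint, and
   within-range environmental means, plus each cell's median log range
   size (the assemblage response).
4. **Two-level regressions** — cross-species (one observation per
   species) and assemblage (one per occupied cell) models of the
   standardized response:
   * OLS with small-sample AICc,
   * PGLS with error covariance `V(λ) = λC + (1 − λ)·diag(C)`, Pagel's λ
     profiled by ML on [0, 1] (`C` = Brownian covariance of the tree),
   * SAR error models `y = Xβ + u, u = ρWu + ε` over 50-km neighbour
     weights in three codings (row-standardized, globally standardized,
     variance-stabilizing), ρ by ML with the eigenvalue log-determinant,
   * all-subsets AICc multimodel inference with full (zero-substitution)
     coefficient averaging over the 95% Akaike-weight confidence set,
   * phylogenetic signal: Blomberg's K with a tip-permutation test and
     Pagel's λ with a boundary-corrected likelihood-ratio test.
5. **Spreading-dye null models** — each species' range is re-placed at a
   random domain position with its size and cohesion preserved (random
   seed cell, then uniform accretion of frontier neighbours). Refitting
   every regression on 100 such randomizations yields null slope
   distributions; observed slopes are judged by one-tailed 0.05/0.95
   percentile rules according to each hypothesis' predicted sign
   (minimum temperature −, elevation −, climate-change velocity +,
   temperature annual range +).

A first-class **synthetic-data generator** (Yule tree, phylogenetically
autocorrelated midpoints, log-normal range sizes with a controllable
latitude slope β and signal λ, cohesive dye-grown ranges, structured
environmental layers) gives every stage a known ground truth, so the
whole pipeline is testable without downloading any occurrence or climate
data.

## Worked example

```python
from rapoport import PipelineConfig, SimulationConfig, run_pipeline
from rapoport.synthetic import simulate_world

sim = SimulationConfig(n_species=60, domain_extent=(0, 0, 1500, 3000),
                       beta_rapoport=0.6, seed=42)
tree, grid, env, pam, occ, truth = simulate_world(sim)

cfg = PipelineConfig(output_dir="demo_out", range_method="alpha_hull",
                     buffer_km=0.0, alpha0=25.0, thinning_resolution=None,
                     n_rep=100, null_models=("ols",), seed=42)
report = run_pipeline(cfg, occ=occ, tree=tree, env=env, grid=grid)

rap = report.results.query("analysis == 'rapoport'")
print(rap[["level", "model", "predictor", "slope", "r2",
           "null_cutoff", "significant"]].to_string(index=False))
```

prints

```
        level model    predictor    slope       r2  null_cutoff  significant
cross_species   ols midpoint_lat 0.689600 0.475548     0.215620         True
cross_species  pgls midpoint_lat 0.689600 0.475548          NaN         <NA>
   assemblage   ols          lat 0.895903 0.802641     0.506545         True
   assemblage   sar          lat 0.887986 0.949736          NaN         <NA>
```

Reading this: the standardized cross-species slope of log range size on
midpoint latitude is 0.69 (generating value 0.6; a 60-species world is
noisy), the spreading-dye null's 95th percentile is 0.22, so the
gradient is flagged significant — range sizes grow poleward beyond what
domain geometry alone produces. The assemblage-level slope is steeper
(0.90) because overlapping ranges pool the same signal, and the SAR fit
absorbs the spatial autocorrelation (pseudo-R² 0.95 vs OLS R² 0.80).
`report.signal` holds Blomberg's K and Pagel's λ for every species
attribute; `demo_out/` receives the species table, assemblage table,
PAM, range polygons (GeoJSON), null slopes, and a run log.

The same analysis runs from files (occurrences CSV, Newick tree, ESRI
ASCII rasters) through a YAML config:

```bash
rapoport simulate config.yaml   # write a synthetic world to disk
rapoport run config.yaml        # full two-level analysis
```

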