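# Methods

## The question and the estimand

Rapoport's rule is the claim that species' geographic range sizes grow
with latitude. The package measures it on an equal-area lattice at two
levels that share one presence–absence matrix (PAM):

* **cross-species** — each species contributes one observation:
  response `ln A` (natural log of range size in km², A = occupied-cell
  count × cell area), predictor its latitudinal midpoint (unweighted
  mean latitude of occupied-cell centroids, signed; an
  `absolute_latitude` switch exists for taxa spanning the equator);
* **assemblage** — each occupied cell contributes one observation:
  response the median `ln A` of the species present, predictor the
  cell's centroid latitude.

Both response and predictors are z-scored (n−1 denominator) before
fitting, so every reported slope is in SD units and comparable across
models and levels. Alongside latitude, four directional environmental
hypotheses are fitted jointly: minimum temperature of the coldest month
(predicted −), elevation (−), climate-change velocity since the last
glacial maximum (+), and temperature annual range (+). At the
cross-species level the environmental predictors are the within-range
means; at the assemblage level the cell values.

## Geometry

Occurrence cleaning is deterministic: exact per-species duplicate
removal, grid thinning that keeps the first record per thinning cell
(half-open cells, no RNG), and spatial-outlier removal that drops a
record when its mean distance to all conspecifics exceeds
Q75 + 2·IQR of those per-record mean distances. The outlier rule needs
meaningful quantiles, so species with fewer than 7 records pass through
untouched. The multiplier 2 and the quantile anchor follow the usual
coordinate-cleaning convention; the rule is intentionally scale-free.

Ranges are extents of occurrence built from at least three distinct,
non-collinear records. The dynamic alpha hull parameterizes alpha as a
circumradius bound in km: the shape is the union of Delaunay triangles
with circumradius ≤ alpha, and alpha grows geometrically
(`alpha0` = 10 km default, factor 1.5, at most 60 steps) until (i) every
record lies in the shape (boundary-inclusive — since all records are
Delaunay vertices this is exactly "every vertex belongs to a kept
triangle") and (ii) the kept triangles form one component under
shared-edge adjacency, which makes the union a single polygon (holes
allowed, point-contact pinches not). Search failure raises; there is no
silent fallback. As alpha → ∞ the alpha shape equals the convex hull,
which the tests exploit as an oracle. Buffers are Minkowski sums
approximated with 1024 segments per quarter arc, so the buffered area of
a convex polygon matches A + P·r + πr² to better than 1e-6 relative.

All geometry lives in projected km. The projection is a spherical Albers
equal-area conic on the authalic radius 6371.0072 km; at 50-km cells the
ellipsoidal refinement would change areas by well under 0.5%, which is
immaterial next to gridding discretization, and the spherical forward /
inverse pair is short enough to verify against a spherical-excess
oracle. Rasterization marks a cell present when the polygon's
intersection with the cell rectangle has positive area (> 1e-9 km²);
edge contact does not count, making the rule robust to polygons aligned
with cell boundaries.

## Statistics

**OLS** uses QR/least-squares with the Gaussian ML log-likelihood;
AICc = AIC + 2k(k+1)/(n−k−1) with k = p + 2 (slopes, intercept, σ²).

**PGLS** assumes residual covariance `V(λ) = λC + (1−λ)·diag(C)` with
`C` the Brownian covariance (shared root-to-MRCA path lengths). λ is
profiled by ML with bounded scalar search on [0, 1] (tolerance 1e-6,
endpoints checked explicitly); when λ is estimated it counts as one
extra AICc parameter. R² is one minus the ratio of GLS residual
quadratic forms (model vs intercept-only under the same V). λ = 0
reduces exactly to OLS, and a star phylogeny makes ML-PGLS equal OLS —
both are regression tests.

**Phylogenetic signal.** Blomberg's K is the observed
MSE₀/MSE ratio over its Brownian expectation, with the GLS grand mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y; its p-value is the share of tip permutations
(999 by default, observed included) whose variance ratio is at least
the observed. Pagel's λ is the intercept-only ML estimate; its test is
a likelihood ratio against λ = 0. Because λ = 0 lies on the boundary of
the parameter space, the LR statistic is referred to the 50:50 mixture
of a point mass at zero and χ²(1) (p = ½·P(χ²₁ ≥ LR); p = 1 when the
estimate collapses to the null). Even so the test is conservative at
moderate tree sizes: on a 64-tip tree the null mass of λ̂ = 0 is ~0.8
rather than the asymptotic ½, so the realized type-I error sits near
1.5% at a nominal 5%. The K permutation test, whose reference is exact
by construction, is calibrated (measured 4–5%). Both numbers are
recomputed by the acceptance script.

**SAR error model.** `y = Xβ + u, u = ρWu + ε`. For fixed ρ the model
is OLS on the transformed system (I − ρW)y ~ (I − ρW)X, and the profile
log-likelihood adds Σ log(1 − ρλᵢ) over the eigenvalues of W; ρ is
maximized on the open interval bounded by the reciprocal extreme
eigenvalues (tolerance 1e-6). With all weights zero the fit reduces to
OLS exactly, and a site with no neighbour keeps a zero weight row
(uᵢ = εᵢ) so OLS and SAR always see the same site set. The reported R²
is Nagelkerke's 1 − exp(−(2/n)(ℓ_model − ℓ_null)) against the
intercept-only non-spatial model, clipped to [0, 1]. Neighbour weights
use a 50-km centroid-distance threshold (0 < d ≤ 50, so a 50-km lattice
has rook neighbours only) in three codings: row-standardized
(rows sum to 1), globally standardized (total weight n), and
variance-stabilizing (rows scaled by √Σbᵢⱼ², rescaled to total n).
Among OLS and the three SAR codings the reported model is the one with
the lowest AIC, near-ties broken by higher R².

**Multimodel inference** fits every predictor subset (intercept-only
included; refused above 12 predictors), weights by AICc, takes the
minimal weight-sorted prefix reaching 0.95 cumulative weight as the
confidence set, renormalizes inside it, and averages each coefficient
with zeros substituted where a model omits the predictor (full
averaging). Full averaging, rather than conditional, was chosen because
it shrinks the coefficients of weakly supported predictors toward zero,
which matches how the averaged slopes are interpreted as effect sizes;
with a single dominant model both variants coincide, which is the tested
identity. The pipeline averages at the cross-species level only; at the
assemblage level the full model is reported directly (there the global
model dominates by construction of the design, so averaging adds
nothing).

## Null models

The spreading dye re-places each species independently: a seed cell is
drawn uniformly from the domain, then one uniformly chosen unoccupied
domain neighbour of the growing patch is added at a time until the
species' observed cell count is reached; if the frontier empties the
species restarts from a fresh seed (50 restarts, then an error naming
the species). Size is conserved exactly and cohesion is guaranteed by
construction; both are re-verified by a flood-fill oracle in the tests.
The domain defaults to the *realized* footprint (cells occupied by at
least one species in the observed PAM) rather than the bounding
rectangle — the former is what constrains real ranges — and is
configurable. Adjacency defaults to queen (8 neighbours), which reduces
placement failures on ragged domains; rook is available.

Each observed slope is compared with 100 re-fitted null slopes
(environmental layers stay fixed; the tables are rebuilt from each
randomized PAM, and PGLS nulls re-estimate λ per replicate). The test is
one-tailed by the hypothesis' predicted sign: significant when the
observed slope exceeds the 95th percentile (positive predictions) or
falls below the 5th (negative), percentiles by linear interpolation over
the replicates only (the observed value is never pooled into its own
reference distribution). Failed replicate fits are dropped and logged;
more than 20% failures aborts the distribution.

## The synthetic generator

`SimulationConfig` defines the study conditions. A Yule (pure-birth)
tree is simulated to `n_species` tips and rescaled to unit depth. True
midpoints are Brownian draws on the tree mapped affinely onto the
central 90% of the domain's latitude span (so seeds never sit on the
boundary). The standardized log cell count is
`u = β·z(midpoint) + ε` with `ε ~ N(0, σ²(λC + (1−λ)I))`; by default
σ = √(1−β²) so `u` has unit variance and the standardized regression
slope equals β in expectation — which is what makes "recover β to
±0.15" a meaningful end-to-end check. Counts are back-transformed
through exp(3.0 + 1.0·u) (median ≈ 20 cells, spanning ~1–250 on a
3200-cell default domain), rounded, clamped to [1, n_cells] with a
warning, and placed cohesively with the same dye kernel as the null
model, seeded at the cell nearest the species' true midpoint (column
drawn uniformly). Occurrences are Poisson(4) points per occupied cell,
uniform within the cell, topped up to at least 3 per species.
Environmental layers impose the field's canonical structure: north–south
elevation ridges (so row-mean temperature stays monotonic in latitude),
minimum temperature falling with latitude and elevation (6.5 °C/km
lapse), annual range rising with latitude, and a last-glacial
mean-annual-temperature surface cooler by 3–7 °C (more at high
latitude) from which climate-change velocity is derived as
|ΔT|/Δt ÷ ‖∇T‖ (Δt = 21 000 yr; cells with gradient < 1e-4 °C/km are
masked to cap the quotient).

What the generator does **not** emulate: sampling bias and
georeferencing error in occurrences, coastlines/irregular domains,
niche-driven (environmentally filtered) range boundaries, range-size
inheritance at speciation, and spatial autocorrelation of the residual
range-size noise. Passing tests therefore demonstrate that the
machinery recovers known structure under clean conditions, not that
real occurrence data meet these assumptions.

## Scaled study sizes

The shipped experiments use sizes chosen to make the Monte-Carlo answer
stable while staying desk-runnable: 20 seeds × (150 species, 40 × 80
grid, 100 null replicates) for the end-to-end recovery runs, 200–500
replicates for the signal calibrations on a 64-tip tree, and 20 seeds on
a 20 × 20 lattice for SAR recovery. The end-to-end runs use alpha-hull
ranges with `buffer_km = 0`: synthetic occurrences are sampled densely
inside every occupied cell, so the 50-km buffer that bridges sampling
gaps in real data has no analogue and would only inflate small ranges
(it remains the default for empirical configs).

## Known limitations

* PGLS assumes the tree's Brownian covariance is exact; measurement
  error in tips is not modelled.
* The SAR eigenvalue log-determinant is computed densely, which is fine
  to a few thousand sites but not for continental 10⁴-cell grids.
* The λ LR test is conservative at moderate n (see above); rely on K's
  permutation p-value when calibrated error rates matter.
* Alpha hulls are limited to a single polygon per species by design;
  genuinely disjunct distributions will be bridged at a large alpha.
* The cleaning rules assume projected coordinates for distances; lonlat
  input is projected before cleaning, so thinning cells are equal-area,
  not equal-angle.
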