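# Methods

## Problem and scope

The package answers a planning question: given a fixed stock of hospital
sites, which p of them should host a specialized service so that the
population's car travel time to the nearest service site is smallest, and
what does the answer imply for accessibility metrics and for policy
scenarios that respect the incumbent configuration? The analysis operates
on three objects: a demand set (hexagon centroids with region densities
and cell areas), a candidate hospital set with a current-service flag, and
an m×n travel-time matrix. Everything else — optimization, heuristics,
metrics, sweeps — is a function of these three.

## Demand model

Each hexagon cell's population is `area × density`, kept fractional so
weighted statistics are exact; rounding is a presentation concern.
Row/column order of the travel matrix follows the demand and hospital
input order everywhere, including file headers; rows are demand points,
columns hospitals.

Two coordinate modes exist. Synthetic mode is planar (km): it removes
projection noise so geometric tests have closed-form oracles. Real-geo
mode is WGS84, reached through an adapter that covers a polygon with
hexagonal-index cells and computes cell areas in an equal-area projection
(EPSG:3035); it requires optional backends (`h3`, `pyproj`) and fails with
an explicit error when they are absent, leaving synthetic mode unaffected.
A two-grid protocol is supported: optimize on a coarse demand set, then
evaluate the chosen sites on a finer one (the library keeps this a
composition of `solve_scenario` and `evaluate_site_set` /
`nearest_assignment` rather than a special code path). Cells clipped by
the country border keep their full hexagon area — a small, documented
upward bias in border populations.

Region densities are joined to centroids by centroid containment; a
centroid on a region boundary takes the lowest region id, a deterministic
tie-break.

## Synthetic country generator

The generator emulates the statistical structure of a national setting at
one tenth of its size (defaults in `SyntheticCountryConfig`):

* **Regions** — 40 Voronoi cells of uniformly sampled seeds in a 300×360 km
  rectangle; irregular convex shapes resembling administrative districts.
  Each draws an urbanization class (urban/intermediate/rural, shares
  0.25/0.40/0.35, close to the European region-type mix) and a density
  uniform in its class range: 500–3000, 150–500, 40–150 persons/km² —
  spanning realistic European district densities.
* **Demand grid** — a pointy-top hexagonal lattice with 10.5 km spacing
  (cell area `s²·√3/2 ≈ 95.5 km²`), ~1140 centroids, mirroring the ~10,900
  cells of the full-scale coarse grid at 1/10 the count.
* **Hospitals** — 100 sites sampled without replacement at demand
  centroids with probability ∝ `density^bias` (default bias 1), of which
  31 are flagged as current service sites by the same biased draw —
  mirroring the full-scale 1023 acute / 315 service hospitals and the
  empirical concentration of hospitals in populous areas. Sites coincide
  with centroids so zero travel time is attainable and degenerate cases
  are exercised.
* **Travel** — minutes = `60 · detour · distance / speed` with speed
  70 km/h and detour factor 1.3 (road-network circuity); Euclidean
  distance in planar mode, haversine in WGS84.

All stages are deterministic given the config seed; artifacts embed the
config and seed in sidecar JSON and never embed timestamps, so a fixed
config reproduces byte-identical files.

What the generator does *not* emulate: within-region density gradients
(densities are piecewise constant), real road-network topology (travel
time is circuity-scaled straight-line distance, so no mountain passes or
river crossings), and any correlation between hospital capacity and
location. Tests passing on synthetic data therefore validate the
*machinery* — model correctness, scenario logic, metric identities,
determinism — not the magnitudes any real country would produce.

## Exact optimization

The p-median MILP is built explicitly (objective `Σ x·w`; assignment,
linking and cardinality constraints) and solved with HiGHS branch-and-cut
via `scipy.optimize.milp`. Numerical choices:

* **Assignment relaxation.** `x` variables are declared continuous in
  [0,1] while `y` stays binary: for any integral `y` an optimal `x`
  assigns each demand point wholly to its cheapest open site, so the
  formulation is exact for the objective and much faster at scale. The
  reported assignment is always re-derived from the open set by
  nearest-open-in-w, never read from `x` (which may be degenerate at
  solver tolerance); ties take the first hospital in column order.
* **Linking.** Per-pair `x ≤ y` is the default (tight LP relaxation);
  Big-M `Σ_c x ≤ M·y` with `M = m` — the tightest valid constant — is the
  memory-saving alternative. Both must and do return equal objectives.
* **Scenarios.** Prioritized mode restricts candidates to the service set
  (p below the current count), pins the service set open (p above), or
  returns the current configuration without invoking a solver (p equal).
  Infeasible cardinalities (p exceeding the candidate pool) yield status
  `infeasible`, not an exception.
* **Tolerances.** Integrality tolerance 1e-6; the reported objective is
  recomputed as `Σ_c min_{open} w` and checked against the solver value at
  1e-6 relative. Objective ties between site sets are accepted — tests
  compare objectives, not site sets, except through the enumeration
  oracle's lexicographic tie rule (first optimum in lexicographic
  candidate order).
* **Oracle.** `brute_force_pmedian` enumerates all feasible open sets
  (refusing, never sampling, above a subset cap of 2×10⁶) and anchors the
  solver's correctness in the suite.
* Candidate pruning (restricting each demand row to its K nearest sites)
  is deliberately not implemented as a default path; the exact model is
  solved in full at the package's scales.

## k-means heuristic

Default variant: observations are demand rows of W (features = hospitals),
Lloyd's algorithm with k-means++ seeding, 10 restarts, seeded and
deterministic. Each cluster maps to the hospital with the minimal center
coordinate — i.e. the smallest mean weighted travel time from the
cluster's members — which at k=1 provably recovers the exact 1-median.
The phrase "match the cluster center to the nearest hospital" is
ill-defined for a feature-space center; this rule is adopted precisely
because of the k=1 equivalence. A geographic variant (cluster coordinates
with population sample-weights, match centers to travel-time-nearest
hospitals) is available behind `matching="geographic"`. Duplicate targets
are resolved by processing clusters in descending member-population order,
each taking its best not-yet-taken hospital (logged when it fires), so
exactly k distinct sites return. The heuristic's objective is evaluated as
`Σ_c min_{selected} w` — the same quantity the MILP minimizes — making the
dominance inequality `z(k-means) ≥ z*(MILP)` exact and testable.

## Accessibility metrics

"Weighted" statistics are population-frequency-weighted statistics of the
minutes (weights = cell populations), which keeps them on the minute
scale; the literal algebra of `w = p·t` would yield person-minutes.
Medians and IQRs use the lower weighted quantile without interpolation
(smallest value whose cumulative weight reaches q of the total):
order-statistic exact, reproducible, and slightly conservative relative to
interpolating conventions on small samples. The threshold share uses
strict inequality (`t > 40` minutes, "exceeding"). Stratification
partitions demand by urbanization class; class-level populations above
threshold sum exactly to the overall value. Distribution comparisons run
on unweighted per-centroid minutes: Shapiro-Wilk per sample
(deterministically subsampled to ≤ 5000) and the two-sided Mann-Whitney U
with tie-corrected normal approximation; the reported U counts pairs
(a > b) plus half the ties. Change reports emit absolute and relative
deltas for every field, with proportions additionally in percentage
points; zero baselines report an undefined (NaN) relative change, never
infinity.

## Quantity sweeps

For a grid of p values the sweep re-optimizes, evaluates the chosen sites
on the evaluation grid, and tabulates objective plus headline metrics.
The liberal objective is non-increasing in p (feasible-set nesting) and is
asserted at run time; evaluation-grid means are left unconstrained —
re-optimizing with fewer sites can reduce the weighted mean while raising
the unweighted one, a real phenomenon of weighted location-allocation, so
monotonicity is only ever claimed for the optimization objective.
Prioritized sweeps do not assume nestedness of the add-on sites across p;
each p re-optimizes.

## Problem sizes

The default synthetic country (~1140 demand cells, 100 candidates, 31
service sites) solves a full liberal p-median in well under a minute and a
two-mode quantity sweep over p ∈ {20, 25, 30, 35, 40} in a few minutes;
the oracle-equivalence bank uses m ≤ 40, n ≤ 10, p ≤ 4 where exhaustive
enumeration is instant. These sizes were chosen so the entire suite,
including two end-to-end determinism runs, completes comfortably on a
single CPU.

## Known limitations

Travel is car-only with uniform conditions; no capacity, staffing or
regulatory constraints; boundary cells keep full hexagon area; the
synthetic travel model has no network topology; whether the original
analysis weighted its statistical tests by population is unknown — tests
here are unweighted, and the weighted-quantile convention is one of
several the reported magnitudes admit.
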