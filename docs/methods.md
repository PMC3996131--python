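# Methods

This note documents the models, conventions and numerical choices behind
`sevnet`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or the acceptance script
does not itself compute.

## 1. Network model

A spatial network is a planar multigraph. **Links** — the unit of
analysis throughout — are polylines joining two adjacent junctions, or a
junction and a dead end; **nodes** are shared endpoints. Coordinates
must be in a projected CRS in meters; no reprojection is performed, only
a plausibility warning when every coordinate lies within ±180 (which
looks like lon/lat).

Construction details:

- Endpoints closer than `snap_tolerance_m` (default **0.5 m**, the
  vertex-jitter scale of digitized road data) are merged into one node,
  which keeps the coordinate of the first endpoint seen — so rebuilding
  an already-snapped network is a no-op.
- Each link precomputes its arc length and its **internal angular
  cost**: the sum over interior vertices of the deflection angle, where
  deflection is 180° minus the interior angle (0 for straight
  continuation, →180 for a hairpin).
- Loop links (both ends on one node) are allowed but flagged;
  MultiLineString inputs are split into parts with derived ids rather
  than rejected, because that dialect is common in exported road data.
- A link's analysis **weight** defaults to 1: all aggregation and trip
  generation counts links, never meters, which makes densely subdivided
  (inhabited) areas dominate over long empty roads.

## 2. Radius-limited subsystems

For an origin link, the analyzed surroundings are all parts of the
network within network distance r of the link's **center** (half arc
length by default; an *angular center* — the first arc position at which
cumulative deflection reaches half the link's total — is available by
flag, and the two coincide on straight links).

Distances are Euclidean meters along the network (Dijkstra from the
origin point, expanding through both link ends, truncated at r). Within
a link with end distances d_A, d_B and length L, the distance at arc
position s is min(d_A + s, d_B + L − s) (plus |s − s₀| on the origin
link itself), so the included set is a union of at most two intervals,
each anchored at an end.

- **Continuous space** (default, the `c` suffix): boundary-crossing
  links contribute exactly those intervals, with included weight
  P = (included fraction) × weight. A link may contribute two disjoint
  partial intervals, one per end.
- **Discrete**: a link is a member only if its entire geometry lies
  within r. The origin link is always a member in both modes.

## 3. Angular geodesics

Route statistics minimize cumulative angular change: interior-vertex
deflections plus turn angles at nodes (the angle between the incoming
and outgoing travel directions; degree-2 nodes are ordinary geometric
turns, i.e. straight continuation costs 0 whatever the node degree).

Conventions that needed fixing and are therefore isolated and tested:

- **Representative points**: a destination is represented by the
  midpoint of its included interval (the link center for fully included
  links). Partial destinations are entered from the end their interval
  is anchored to; the partial tail of the geodesic adds the deflections
  strictly between the entry end and the representative point.
- **Confinement**: geodesics may traverse only fully included links. In
  continuous mode every member is reachable (the distance-minimal path
  to it is itself fully included); in discrete mode destinations can be
  unreachable and are then dropped from route-based metrics and counted
  (`n_dropped`).
- **Tie-breaking**: route cost is the lexicographic tuple (angular cost,
  network length, link-id path in lexicographic order). The third
  component is not cosmetic: routes whose turns all have one sign
  between the same start and end directions tie *mathematically* in
  total angle, and betweenness flow allocation depends on which route
  wins. The engine's Dijkstra over (link, arrival-end) states carries
  the full tuple; the brute-force reference used in the tests applies
  the identical rule, and both use the same elementary angle primitives
  so that tied routes evaluate to bit-identical costs.

## 4. The 16 metrics

With destinations y ≠ origin, weights P(y), angular distance d_θ,
network length l, crow-flight length c:

| metric | definition |
|---|---|
| Links | Σ P over members (member count in discrete mode) |
| Length | included network length, m |
| NQPDA | Σ P(y) / max(d_θ(y), δ), δ = 1° floor (collinear destinations) |
| MGLA, MCF, MAD | P-weighted means of l, c, d_θ over destinations |
| DivA | P-weighted mean of l/c per route (routes with c ≈ 0 excluded) |
| Jnc, Con | junction count (degree ≥ 3 nodes within r) and the sum of their degrees |
| BtA | Σ over ordered pairs (y,z), z in radius of y: W(y)·P(z)·σ(y,z,x) |
| TPBtA | as BtA with trips normalized per origin: W(y)·P(z)/ΣP(R_y)·σ |
| TPDA | destination popularity: Σ_y W(y)·P(z)/ΣP(R_y), gated on radius membership |
| HullA, HullP | area and perimeter of the convex hull of all reached points (included-portion vertices plus boundary cut points) |
| HullR | max crow-flight distance from the origin point to any reached point (≤ r; = r iff a straight reachable ray exists) |
| HullSI | HullP / (2√(π·HullA)), = 1 for a disc |

σ endpoint convention for the betweenness family: 1 for strictly
intermediate links, ½ for the origin and destination of a proper pair,
⅓ for the self pair (included). This is one small function so that
alternatives remain testable. TPDA is gated on membership, not geodesic
existence; the alternative reading matters only in discrete mode.

Degenerate hulls: point sets collinear within floating point (hull area
< 1e-6 m²) report HullA = 0, HullP = twice the extent, HullSI missing.
Missing values propagate pairwise (per metric, not per link) through
aggregation and correlation.

A vectorized fast path (`hullr_profile`) recomputes HullR alone from
per-origin distance fields for dense radius sweeps; it is tested to
agree with the full engine exactly.

## 5. Aggregation

Unit polygons are dilated by **30 m** (round joins, fine enough that a
point 30 m from a straight edge is included with < 0.1 m error) before
intersecting with full link geometry, so boundary roads count in every
adjacent unit; unit values are unweighted link means. Empty units are
retained with missing values and a warning.

## 6. Statistical stage

- **Screen**: pairwise-complete Pearson r of each (metric, radius)
  column against the outcome, two-sided p, Bonferroni multiplier equal
  to the number of cells actually tested (80 for the full grid), with
  the relaxed ×16 reading (radii as per-metric calibration) reported as
  metadata. Zero-variance columns yield missing cells excluded from the
  best-cell selection.
- **Standardized OLS**: outcome and predictors z-scored with ddof = 1
  (the 0/1 urban flag included, unless `standardize_binary=False`);
  intercept absorbed, residual df = n − p − 1. With one predictor the
  coefficient equals Pearson r to 1e-12. Exact collinearity raises an
  error naming the dependent columns (identified from the smallest
  singular vector). Listwise deletion in regressions, pairwise in the
  screen.
- **Tertiles**: units ranked by deprivation (ties broken by unit id for
  a reproducible partition) and split into equal thirds; the multivariate
  model is re-fit within each with within-tertile standardization.
  Constant-within-tertile predictors are dropped and flagged.
- **Radius sweep**: HullR is recomputed at each radius and re-aggregated
  with the assignment held fixed (one 30 m buffer for all radii); the
  curve of bivariate correlations and its argmax radius are returned.

## 7. Synthetic worlds

The generator emulates the *statistical shape* of a severance study, not
any real geography:

- **Network families**: grids and jitter-perturbed grids (connected,
  low severance), single-link zigzags and circular loops (closed-form
  hull geometry), cul-de-sac estates (a spine with tree-like dead-end
  interiors — high severance by construction), linear settlements (one
  near-straight road with short stubs — high HullR), and a **composite**
  borough tiling these families over a meta-grid with straight
  connectors (default 10 × 10 tiles ≈ 2,000 links at 100 m street
  spacing, a typical UK urban block scale).
- **Districts**: a Voronoi partition of the buffered bounding box around
  k sampled link centers (default k = 325). Cells tile the region
  exactly and each contains its seed link, so no district is empty. This
  is a geometric stand-in for census districts, sufficient for testing
  aggregation; it does not mimic population-based districting.
- **Outcomes**: deprivation ~ N(0,1) (optionally U-coupled to HullR so
  poorly connected districts land at either deprivation extreme, with a
  random sign per district — the quantitative form of that coupling is a
  modeling choice); urban = indicator of above-median link density;
  cohesion = β_dep·z(deprivation) + β_hull·z(HullR600c) + β_urb·z(urban)
  + ε. Defaults β = (−0.42, +0.26, −0.10) with noise calibrated from the
  empirical covariance of the generated predictors so the population r²
  is 0.249 (orthogonality is not assumed; it fails under the U-shape).
  An optional per-tertile β_hull (default pattern 0.21/0.31/0.41,
  least → most deprived) produces the severance-by-deprivation
  interaction. All draws come from named substreams of one seed, so
  changing the district count never perturbs network geometry and equal
  seeds give bit-identical worlds.

One scale identity is worth stating: standardized coefficients are
invariant to the outcome's scale, so with noise calibrated to a target
r² the *population* standardized coefficients equal
β·√(r²_target / βᵀΣβ) (a factor ≈ 0.99 at the defaults). The generating
β is recovered exactly on the raw-coefficient scale in the noiseless
limit; recovery tests of the standardized coefficients use a 2-SE
criterion, which this ~1% attenuation does not approach.

What a green test therefore establishes: that the engine computes the
stated geometry exactly (oracle equivalence, closed forms, invariants)
and that the statistical stage is calibrated (≈5% null rejection,
family-wise control under Bonferroni) and recovers planted effects of
the study-patterned magnitude at n = 325. It does not establish anything
about real road networks: synthetic layouts lack one-way systems, grade
separation, pedestrian-only paths, and realistic density gradients, and
the outcome model is linear-Gaussian by construction.

## 8. Performance notes

Per-origin work (one truncated Dijkstra, per-radius subsystems, one
angular Dijkstra per radius) is independent across origins —
embarrassingly parallel, though the implementation is single-threaded.
The full 16-metric table at five radii on a ~500-link borough takes
about a minute on one CPU; HullR-only sweeps on a ~2,000-link borough
at 15 radii take ~20 s via the vectorized fast path.
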