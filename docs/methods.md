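# Methods

## Model

Health-care access is a two-stage shortest-path problem on an undirected
road graph. Edge weight is travel time in minutes,

    t(e) = (length_m(e) / 1609.344) / speed_mph(class(e)) × 60,

with speeds assigned per OpenStreetMap highway class (trunk 65, primary 55,
secondary 45, tertiary 30, unclassified 25, residential 25, service 15,
living_street 25, road 35, connector 35 mph). No turn costs or one-way
restrictions exist: a traveller may turn in any direction at any junction.
These speeds are estimates; the class table is overridable per run.

For an origin i, a set S of POCT-equipped sites and the single care center
c, the spatial care path is

    stage 1:  d(i) = argmin_{s ∈ S} t*(i, s)        (closest facility)
    stage 2:  t_care(i) = t*(d(i), c),

where t* is the network shortest-time metric (Dijkstra). Total time to care
is t_diag + t_care. Because stage 1 is greedy, total time can strictly
exceed the direct origin→care time — the "backtracking" pathology the
scenario analysis is designed to expose. The triangle inequality of t*
guarantees t_total ≥ t*(i, c) always; a dedicated fixture
(`synth.backtracking_region`) certifies the strict case.

The care center is always a permissible diagnosis site in every scenario: a
patient who reaches the tertiary hospital is diagnosed there. Anything else
would route patients *away* from the care center they are standing in.

## Network construction

Raw road polylines are integrated GIS-style: all vertices within the snap
tolerance (default 10 m, configurable; 0 disables merging beyond exact
coincidence) are clustered by connected components of the proximity graph
and replaced by their centroid. Polyline endpoints always become junctions;
interior vertices become junctions only where they merge with another
polyline (a crossing), splitting both lines there. Zero-length segments
after merging are dropped with a warning. Unknown highway classes are
rejected, not defaulted, so data errors surface immediately.

Off-network points (places, facilities) attach via a straight connector
segment (class "connector", 35 mph) to the nearest point of the nearest
*road* segment — connectors are never targets, so a point cannot chain onto
another point's connector. The target segment is split at the foot point,
conserving total length to float precision; this split is required for
correct routing even though a GIS "closest facility" layer may treat the
connector as merely touching the line. Ties in nearest-segment distance go
to the smallest segment id; a point within 1e-6 m of an existing junction
attaches directly with no connector.

## Access summaries

Weighted summaries use populations as frequency weights (a village of
10 000 counts as 10 000 identical travellers):

    μ_w = Σ wᵢ tᵢ / Σ wᵢ,   σ_w = sqrt( Σ wᵢ (tᵢ − μ_w)² / Σ wᵢ ).

With equal weights this reduces exactly to the unweighted mean/SD (ddof 0).
Unreachable origins are excluded with a logged count rather than failing
the run, so partial networks remain analyzable. Histograms of total time use
left-closed, right-open 15-minute bins. Percent decrease over a baseline is
100 (t_cur − t_alt)/t_cur, computed on unrounded means and then rounded to
one decimal for table parity; published comparison tables for the emulated
region are consistent with this plain ratio-of-printed-means convention
(one published cell, the rearrange-strategy total, is not arithmetically
consistent with its printed means and is excluded from parity checks).

## P-median placement

Device placement is a P-median problem with required sites: choose S,
|S| = k, required ⊆ S ⊆ candidates, minimizing Σᵢ wᵢ minₛ∈S t(i, s). Travel
times are precomputed into a demand × candidate matrix (one single-source
Dijkstra pass per candidate; valid in both directions because the graph is
undirected). Impedance is linear with no cutoff. The objective covers the
diagnosis stage only, matching how placement policies are typically framed;
minimizing total time-to-care instead is possible by passing a matrix of
origin→site→care totals, but is not the default.

Two solvers share the evaluation code:

- `solve_exact` — exhaustive enumeration over the free candidates, refused
  above a configurable 200 000-subset cap; ties resolved to the
  lexicographically smallest site set. This is the oracle.
- `solve_heuristic` — greedy addition from the required set, then
  best-improvement single-swap (vertex-substitution) descent, best of n
  seeded restarts (restart 0 is the deterministic greedy start). The
  heuristic can never beat the exact optimum and attains it on every
  shipped fixture; this is asserted, not assumed.

The three strategies map onto constraints: rearrange (required = ∅,
k = |existing|), keep-plus-k (required = existing, k = |existing| + k_extra),
rearrange-plus-k (required = ∅, same k). Since rearrange-plus-k relaxes
keep-plus-k, its optimum is never worse — a property the test suite checks
on random regions.

## Synthetic regions

The generator emulates the *structure* of a rural health-access study area,
not any particular geography. Networks are either a square grid (2 km
spacing) or a Delaunay triangulation of uniform random junctions thinned to
a random connected partial graph; edge classes are drawn from a mixture
dominated by minor roads (trunk 3 %, primary 7 %, secondary 10 %, tertiary
15 %, unclassified 25 %, residential 30 %, service 5 %, living_street 3 %,
road 2 %) — a hand-set profile resembling rural OSM class frequencies.
Places are jittered off distinct junctions; settlement types follow a
mixture proportional to observed counts in the emulated region
(1 city : 1 suburb : 5 towns : 1303 villages : 83 hamlets) and carry the
type-default populations (100 000 / 100 000 / 20 000 / 10 000 / 200).
Facilities sample junctions with probability proportional to local place
density, echoing the tendency of facilities to cluster near settlements;
the default roster (16 hospitals : 40 health-promoting hospitals) keeps
roughly the observed ≈1:8 tier ratio at desk scale. One hospital — by
default the one farthest (network time) from the population-weighted
centroid place — is relabelled as the care center, and the current device
roster (default 14, a free parameter standing in for an unpublished survey
count) is drawn from the remaining hospitals. Everything is driven by one
`numpy` Generator, so a fixed seed reproduces a region byte-for-byte.

What the generator does *not* emulate: real road geometry and density
gradients, OSM tag richness beyond the highway class, incomplete/erroneous
mapping, demographic structure beyond one population number per place, and
the strong east–west asymmetry of a real single-care-center region. Passing
tests therefore certify the algorithms and their invariants, not any real
region's point estimates — the published headline means depend on
proprietary inputs and are checked only at the level of printed-table
arithmetic.

Fixture sizes are deliberately small so the suites run in seconds: the
enumeration-certified P-median fixture has 12 candidates and 24 places
(optima for k = 1..4 recomputed at call time by an enumeration loop
independent of the solvers); the random-region property suites use 36-
junction grids with ~14 places and 8 facilities.

## Numerical choices

- Units: meters, minutes, mph as tabulated; 1 mile = 1609.344 m.
- Coordinates are assumed planar meters (pre-projected); no CRS handling.
- Tie-breaks are deterministic everywhere: smallest segment id for
  connector targets, smallest facility id for closest-facility and
  assignment ties, lexicographically smallest site set for solver ties.
- Snap clustering uses a cKDTree pair query; cluster centroids are the
  merged coordinate, making rebuilds idempotent.
- Comparisons use strict-improvement updates with a 1e-12 slack in the
  swap descent to avoid cycling on float noise.
- Split-segment ids use "." suffixes (`R0001.a`) because "#" is reserved
  for comment headers in the CSV dialect.

## Limitations

- Stage-1-greedy routing is faithful to closest-facility practice but not
  globally optimal for total time to care; the backtracking fixture shows
  the gap.
- The P-median model is uncapacitated; no coverage variants.
- Speeds are class constants — no congestion, time-of-day, or elevation.
- The exact solver is exponential by design; large instances must use the
  heuristic, which carries no optimality guarantee beyond the swap-local
  optimum.
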