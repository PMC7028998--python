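# Methods

This note records the model as implemented, the defaults and why they are
set where they are, the numerical choices, and what the synthetic fixtures
do and do not establish.

## The world grid

Cells are the vertices of a Class-I geodesic subdivision of the
icosahedron (frequency *f* gives 10 f² + 2 cells; every cell has six
neighbours except the 12 pentagonal cells at the icosahedron vertices).
Vertex positions are produced by subdividing each face in its plane and
mapping the lattice to the sphere with an equal-area polyhedral (Snyder
style) face projection, solved by Newton iteration on the spherical-excess
equation (tolerance 1e-14, ≤30 iterations). Cell areas are computed
exactly as barycentric-kite solid angles of the dual tessellation, so they
sum to the full sphere (4πR², R = 6371 km) by construction; the resulting
spread is ~0.7% (sd/mean) at the default resolution, with the pentagons
~25% smaller than hexagons.

The default resolution targets a mean cell area of 23,320 km² — the value
back-computed from the two printed range areas (131 cells ≈ 3.05 Mkm²,
180 cells ≈ 4.20 Mkm²) — which selects f = 47: 22,092 cells of
23,088 km², mean internode spacing 164 km. An aperture-3 hex hierarchy
(ISEA3H-like) would hit the back-computed cell count slightly more closely
but needs hex lattices straddling face edges at odd resolutions; the
Class-I construction reproduces every property the simulator relies on
(equal areas, 5/6-neighbour adjacency, the printed range areas within
~1%) at a fraction of the complexity, so it is the design chosen here.
Coarser frequencies (f = 3–12) serve as test worlds.

Hemispheres: a cell is WH iff its centroid longitude lies in [−180°,
−30°); the boundary meridian itself is EH (half-open convention, matching
"west of 30°W" read literally). Distances are haversine great circles on
the R = 6371 km sphere.

## Environment

Seasons are fixed month windows: NS = May–August, NW =
November–February; the four transition months enter only the annual
means. Energy supply per cell and season is E_S = μ·log₁₀(NPP + 1) with
negative NPP clamped to zero first; NPP is the mean of the season's
monthly values (gC m⁻² month⁻¹) before the log. μ = 65 by default; E_S is
linear in μ, so μ only rescales the world's carrying capacity. Ice cells
get E_S = 0 and are excluded from seeding and growth.

The climatic space is (z(T_ann), z(log₁₀(P_ann + 1))), standardised with
the sample standard deviation over habitable cells of the slice being
processed (per-slice standardisation; the +1 offset handles zero
rainfall). A zero-variance dimension raises by default; callers that
accept degenerate spaces (uniform toy worlds) get that axis zeroed, so it
contributes nothing to climatic distances.

## Range options

Per slice and hemisphere: 400 options of 131 cells (WH) and 600 of 180
cells (EH) by default. Seeding weight 1/(1 + S_h) over habitable cells of
the hemisphere; the option pool is generated once per slice before any
species exists (S_h = 0), the reading of "generate the pool as a per-slice
preamble". Growth: the seed's climate-space position is the initial
optimum; two neighbours of the seed join first; thereafter each iteration
redefines the optimum as the mean position of the occupied cells and
annexes ⌈0.25·|frontier|⌉ frontier cells, sampled without replacement with
weight m·2(d + 1)⁻ˣ (m = number of occupied neighbours, d = climatic
distance to the optimum, x = 30). Weights are normalised in log space so
the steep exponent cannot underflow. The final batch is truncated —
dropping the lowest-weight selected cells first — so sizes are exact. A
range whose frontier empties early (islands, ice pockets) is discarded and
re-seeded, up to 50 attempts per option. Option centroids are
area-weighted spherical means of member-cell centroids, renormalised to
the sphere.

## Assembly loop

Candidates are all ordered (NS-range, NW-range) pairs within one
hemisphere: n² pairs per hemisphere and step, the diagonal being the
residents. Ordered pairs with subsequent breeding-season assignment are
equivalent to counting each unordered pair under both season roles, so no
candidate is lost. E_prod is evaluated against the field as of the start
of the step; the argmax is selected with a deterministic first-occurrence
tie-break (lower NS option id, then lower NW option id). The breeding
season is the one with the higher seasonal production
β·E_A^s − (BE_U + α·d_m); since the cost term is season-symmetric this
reduces to the richer season, with ties going to NS.

Depletion removes the fraction β of each member cell's own current E_A in
the occupied season (NS range → NS layer, NW range → NW layer; a
resident's congruent ranges hit both). Per-cell proportional removal is
consistent with E_assim = β·mean(E_A) and keeps 0 ≤ E_A ≤ E_S without any
reallocation logic. Because depletion is monotone, the best achievable
E_prod is non-increasing across steps and the loop terminates.

Stop rule (configurable): default `eprod_nonpositive` stops when the best
E_prod ≤ 0; `assim_below_beu` stops only when the best candidate's annual
assimilation falls below BE_U. The two differ algebraically (E_prod ≤ 0 ⟺
E_assim ≤ 2(BE_U + α·d_m)), the default being the stricter bar, hence
fewer species. Hemispheres are simulated independently (EH first, then
WH, ids continuing) and merged for global metrics; their option pools and
energy cells are disjoint, so the order does not affect the result.

Parameters: β = 0.012 (scan grid 0.003–0.035 in steps of 0.001; below
~0.003 on realistic supply fields not a single species is viable),
α = 6.45×10⁻⁵ per km, BE_U = 1, μ = 65, x = 30.

## Flight energetics

α = F_W / (F_S · BMR_S) with F_W = 0.257 M^0.763 W, F_S = 6.4773 M^0.13
m/s (converted to km/s), BMR = 6.7141 M^0.6452 ml O₂/h, 172 ml O₂/h per
W, and 182 × 86,400 = 15,724,800 s per season. The exact chain gives
BMR_S = 6.138×10⁵ J at 1 g and α = 6.46×10⁻⁵; the conventional rounded
coefficient 6.15×10⁵ gives α = 6.45×10⁻⁵, which is the default (both are
exposed). The residual mass exponent 0.763 − 0.13 − 0.6452 = −0.0122
makes α vary by only (1000/5)^0.0122 ≈ 6.7% across 5–1000 g — treated as
mass independent; all virtual species share α.

## Patterns, scoring, scans, time series

A migrant contributes to the breeding-migrant map on cells of its breeding
range *only* ("present only during the breeding season"): cells in both
seasonal ranges count in neither migrant map by default (configurably as
resident occurrences). Scoring sums the three per-cell Pearson
correlations (breeding migrants, non-breeding migrants, residents) between
simulated and empirical grids, unweighted across cells; a zero-variance
pattern is excluded with a warning. Scans re-simulate from the pristine
field at each grid point with a shared seed, so option pools are identical
wherever the scanned parameter does not enter their construction. The μ
scan rescales E_S in place (exact, since E_S is linear in μ) rather than
rebuilding the energyscape. Time-slice runs are fully independent
("no memory"): each slice gets a sub-seed derived from (master seed,
slice id), so a slice's randomness does not depend on which other slices
run alongside it, and identical slices reproduce exactly.

## Synthetic planets

The generator emulates the *structure* of downscaled climate-model fields,
not any particular reconstruction: annual-mean temperature 27 °C at the
equator falling by 50 °C (sin² of latitude) to the poles; a seasonal cycle
of amplitude 22·sin|lat| °C, anti-phased across hemispheres with the July
peak in the north; precipitation belts of 150 mm/month wet tropics,
dry subtropics, a 60 mm/month temperate band at ~50° and a 15 mm/month
floor, with a 30% summer-wet modulation; Gaussian noise (0.8 °C, 8
mm/month) per cell and month; ice poleward of 72°N/65°S in the present
fixture. These are round numbers chosen to match the modern Earth's
zonal-mean climate to first order, set once and not revisited. NPP is
Liebig's minimum of a logistic temperature term and a saturating moisture
term with classic climate–productivity constants (saturation 3000
gC m⁻² yr⁻¹, moisture constant 6.64×10⁻⁴ per mm annual precipitation; the
monthly moisture input is annualised ×12, the result divided by 12 back to
a monthly rate), keeping monthly NPP on the gC m⁻² month⁻¹ scale that
makes μ = 65 meaningful. The glacial fixture cools the planet uniformly
by 6 °C and extends northern ice to 50°N.

What the fixtures do not have: continents and oceans (every non-ice cell
is land and habitable), orography, interannual variability, zonal
asymmetries (monsoons, ocean currents) and realistic land fractions per
hemisphere. Passing tests on them demonstrates the model's internal logic
and its qualitative limit behaviours — not that any particular empirical
richness pattern would be matched; with these energy fields the viability
threshold on β sits near 0.007 (it is 2·BE_U divided by the best pair sum
of seasonal mean supplies, a property of the field, and the fixtures are
poorer than Earth) and the migrant proportion at the default α is a few
percent rather than tens of percent.

## Numerical choices and degenerate inputs

- Newton solves of the equal-area projection clip arccos/arcsin arguments
  to [−1, 1]; the inverse is exact to ~1e-12 on the sphere.
- Frontier sampling is `Generator.choice` without replacement on
  log-space-normalised weights; an all-zero weight vector cannot occur.
- Ties in candidate selection resolve to the first maximum in C order,
  making runs bit-reproducible under a fixed master seed; per-stage
  randomness is drawn from named substreams of the master seed.
- Empty worlds (all ice, zero supply) saturate at step one with zero
  species rather than erroring; an all-ice hemisphere fails option
  generation loudly.
- Range sizes of 1 and 2 are legal: the two-neighbour batch is truncated
  like any other batch.

## Scale of the shipped analyses

Tests and the acceptance checks run on coarse worlds (frequencies 3–12,
92–1,442 cells) with option pools and range sizes scaled to the grid
(e.g. 40/60 options of 9/12 cells), the package's chosen desk scale;
full-resolution multi-slice reconstructions use the same code paths with
the default parameters and are a matter of compute, plus real
(reconstructed) climate/NPP/ice inputs supplied as per-hexagon CSV.

## Known limitations

- Travel cost is the great-circle distance between range centroids: no
  seas, mountains, stopovers or winds.
- All species are functionally equivalent (one α, one BE_U, no abundance
  structure, no within-season movement).
- NetCDF rasters are not read directly; inputs arrive as per-hexagon CSV
  tables (one row per cell, monthly columns).
- The grid is built at a single default resolution (plus coarser test
  resolutions); it is not a general DGGS toolkit.
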