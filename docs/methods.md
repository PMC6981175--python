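# Methods

This note documents the models implemented in `adfield`, the conventions
adopted where the underlying method leaves choices open, the parameter
defaults and why, what the synthetic-data generator does and does not
emulate, and known limitations.

## Lattice domains and geometry

A domain is a set of land cells on a regular lattice.  For a 1°-grid the
cell spanning `[lon, lon+1) × [lat, lat+1)` has its center at
`(lon+0.5, lat+0.5)`; all centroid arithmetic operates on raw coordinate
degrees with no cos-latitude area weighting, because the centroid
formulas are defined directly on coordinates and any projection
correction would change the statistic.  Adjacency is rook (4-neighbor)
by default — the conventional spreading-dye choice, which preserves the
strictest notion of range cohesion — with queen (8-neighbor) available
everywhere via `adjacency_mode`.

Boundary distances are graph steps, not kilometres: a cell of an
ecoregion is at distance 0 iff one of its lattice neighbours belongs to
a different ecoregion **or lies outside the domain** (a coastline
reading: the outer edge of a region bounds it just as an ecotone does).
A consequence worth knowing: every cell of a 1-cell-wide region touches
the domain edge sideways and is therefore boundary.  Distances elsewhere
are multi-source BFS from the boundary cells, restricted to the region;
they satisfy a 1-Lipschitz property along within-region adjacency edges.
Externally computed distances (e.g. great-circle km) can be substituted
in the ecotone regression without changing its contract.

## Dispersion-field algebra

`D = PᵀP` is computed sparsely; per-cell fields are formed as the column
sums of the rows of P present in the focal cell, so a full N×N product is
never materialised unless requested.  Cells of zero richness are legal
lattice members: they yield all-zero fields with a warning flag, while
ratio statistics (mean cosmopolitanism, centers of gravity) raise,
because 0/0 silently mapped to 0 would poison downstream maps.

## Trimming and asymmetry vectors

Two conventions needed fixing where the method is usually stated loosely:

* **Cutoff semantics.**  A cell k survives trimming at cutoff c iff
  `D[j,k] / s_j ≥ c` — the fraction *of the focal assemblage* shared.
  This makes the focal cell always survive (`D[j,j]/s_j = 1`) and puts
  taxa with different richness on a comparable scale.  The alternative
  normalisation by the maximum off-focal count is available as
  `cutoff_mode="max_offfocal"`; no claim is made about which convention
  any particular empirical study used.
* **Center of the trimmed region.**  The head of the asymmetry vector is
  the shared-count-weighted centroid of the surviving cells
  (`weights="counts"`; unweighted by area via `weights="uniform"`).  For
  the *untrimmed* field the classical mean-of-range-centroids center
  (the average of species centroids x̄_i, ȳ_i) is exposed as
  `center="range_centroids"`; the two coincide in spirit but not in
  value, and both are kept because published usage is ambiguous between
  them.

Vector lengths are coordinate degrees; angles counter-clockwise from
east.  A central region degenerate to the focal cell alone yields a
zero vector with a `degenerate` flag rather than an undefined direction.
Vector-length histograms use 30 equal-width bins over [0, max length],
recorded in the diagram metadata.

Trimming is monotone (larger c, smaller region), centers of gravity are
translation- and reflection-equivariant; both are enforced by property
tests.

## Spreading dye and the assembly models

A range grows from a seed by sampling uniformly among the *frontier*
cells (adjacent to the range, not in it) until the target size is
reached.  "Select a random cell adjacent to the range" is ambiguous
between frontier-uniform sampling and picking a random occupied cell
first; frontier-uniform is the default, the cell-first variant is kept
as `sampling="neighbor_of_cell"`.  The two differ mildly in shape
statistics (cell-first favours bulkier ranges because high-degree
interior cells get more weight); nothing downstream depends on the
choice.  A stalled attempt (frontier exhausted) restarts from a fresh
seed up to 100 times before erroring — bounded, reproducible failure.

* **Energy model** — seed sampled ∝ a nonnegative energy surface,
  expansion unconstrained.  With a uniform surface it reduces exactly to
  the null model (verified distributionally by KS tests on range
  centroids).
* **Ecoregion model** — seed region sampled ∝ per-region occupancy
  weights (default: region cell counts), seed cell uniform within it.  A
  growth step into a cell outside the range's *home* region — defined as
  the seed cell's region, so a range's identity is stable after a
  crossing — carries relative weight 1/penalty, default penalty 30
  (rare but possible crossings).  Weights renormalise over the frontier,
  so a forced crossing (single frontier cell) still occurs; penalty = 1
  reduces to the null model, penalty → ∞ confines the range.
* **Richness-constrained model** — all species grow simultaneously;
  each step samples one (species, frontier-cell) pair with probability
  ∝ the cell's remaining richness deficit (target − current), jointly
  across species; exhausted cells are excluded.  Because placements
  never exceed a cell's target, the precondition
  Σ range sizes = Σ target richness forces exact equality at
  termination.  Cohesion is strict while possible: an attempt that
  stalls restarts (100 attempts), and only when the whole cohesive
  budget fails is adjacency relaxed to graph distance 2, then 3
  ("small gaps"), after which the targets are declared infeasible with
  the stuck species and cells named.  Gaps are therefore a last resort,
  not a shortcut — the relaxed ladder never fires on instances a
  cohesive completion can solve within the restart budget.

  *Limitation:* on sparse targets (many zero-richness cells) the
  deficit space fragments, and instances whose remaining deficits lie
  beyond distance 3 of the stranded species error out.  On a 6×6 domain
  with 15 species of sizes 4–10 all tested instances complete; on an
  8×8 domain at similar fill, 15–35% of null-fauna-derived targets are
  infeasible under this contract.  The deficit weights are normalised
  jointly over species, not per species.

All model randomness flows from a single seeded generator per
simulation; manifests echo the seed, model, penalty, adjacency and
per-species ground truth (seed cell, home region, size).

## The null model and standardized effect sizes

For each needed range size (sizes span 2..N; a size-1 range intersecting
cell j can only be {j} and is handled analytically), a sampling
population of spreading-dye ranges is generated until **every** cell is
intersected by at least `coverage = 100` stored ranges of that size.  A
null dispersion field for cell j draws, for each species present in j,
one stored range of that species' size from among those intersecting j —
uniformly, with replacement, which keeps replicates exchangeable — and
overlays them; the cell's empirical range-size frequency distribution is
thereby preserved exactly.  Repeating R = 1000 times (default) and
pushing each null field through the *identical* trimming and
asymmetry-vector pipeline as the empirical data yields the null
distribution λ; the empirical value ν is summarised as
SES = (ν − μ(λ))/σ(λ) with σ the sample (n−1) standard deviation, the
null-model convention in community ecology.  λ defaults to trimmed
vector lengths (matching the empirical quantity); untrimmed lengths are
available via `trimmed=False`.  σ = 0 yields a flagged NaN rather than
±∞, and per-cell failures are recorded per cell instead of aborting a
map.  Populations persist to a text archive keyed by a domain hash so
1000-replicate runs need not rebuild them.

Type-I behaviour is checked end-to-end: faunas generated by the null
model itself, run through the full pipeline, give per-cell SES pooled
over several faunas with |mean| < 0.1 and sd ≈ 1.

## Ecotone regression

Interior cells of a region are its members below an optional elevation
cap minus an explicit exclusion list (the generalisation of excluding
cells isolated behind highlands).  SES is regressed on boundary distance
by OLS; R², slope, intercept, the slope's standard error and residuals
are reported, plus a one-sample KS test of the standardised residuals
against the standard normal.  Because the residual mean and sd are
estimated from the data, the KS p-value is approximate (the classical
Lilliefors caveat) and is labelled as such.

## The synthetic generator: what it emulates, what it does not

`synth` builds connected lattice continents (near-square rectangles,
4-fold-symmetric discs, two lobes joined by a one-cell isthmus),
partitions them into k contiguous ecoregions by seeded multi-source
growth (balanced in expectation), lays uniform or linear-gradient energy
surfaces, and drives the assembly models to produce faunas.  Range sizes
default to a log-series truncated to [1, N] — the right-skewed shape of
real range-size frequency distributions — parameterised by its mean.
Scenario defaults used throughout the tests keep the mean range size at
roughly 3–16% of the domain, bracketing the relative scale of real
continental faunas.

Not emulated: realistic coastline or ecoregion geometry, climate or
elevation fields with spatial autocorrelation, abundance, taxonomic
structure, or range-map error.  Passing tests therefore demonstrate the
*mechanics* of the pipeline and the qualitative geometric signatures
(null vectors pointing at the continental centroid; penalised faunas
turning over at ecotones with asymmetry growing toward region
peripheries); they do not validate conclusions about any empirical
fauna.

## Problem sizes and numerical choices

Test and acceptance runs use domains of 36–250 cells, faunas of 15–600
species, populations at coverage 100, and SES maps at R = 200 with SES
calibration pooled over six independent faunas (~850 cells); these sizes
give each check comfortable statistical power while keeping a full run
in the low minutes on one CPU.  The production defaults (R = 1000,
coverage 100, penalty 30, cutoffs in 0.5–0.7) are the method's own
standard settings.  Ties in weighted sampling are resolved by the RNG;
all tests and scripts derive every random stream from explicit seeds,
and identical seeds give bit-identical outputs end to end.
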