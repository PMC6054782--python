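# Methods

## Scope and model

The package analyses winter crane surveys in which the flock is the sample
unit: each discrete flock contributes one planar GPS point, one species
label, one survey index and a head count. Counts are carried through the I/O
layer but weight no statistic — all selection and distribution estimates are
per-flock, matching the survey design the package targets. Two species are
analysed fully independently except for the roost-distance comparison.

All geometry is planar Euclidean in meters. Distances are reported in km,
areas in hectares. Geographic (lon/lat) coordinates must be projected before
ingest; the readers reject tables whose coordinates all fall inside the
lon/lat range, since treating degrees as meters would corrupt every
downstream number silently.

## Flock discretization

Groups are merged into flocks by single linkage: two records share a flock
iff they are connected by a chain of pairwise distances ≤ the threshold
(default 500 m), i.e. "discrete" means strictly more than the threshold
apart. Single linkage is the unique order-independent reading of a pairwise
separation rule; it is implemented as connected components of the ≤-threshold
proximity graph (k-d tree pair search + sparse graph components). Labels are
renumbered by first appearance so output is deterministic under input order.

## Use, availability and electivity

Availability is a fixed landscape property: class area as a share of the
total area of the available classes (farmland, marshland, grassland by
default). Flocks assigned to other classes (e.g. a single woodland flock)
are excluded from the use denominator and reported as an excluded count
rather than silently dropped.

Ivlev's electivity s = (a − b)/(a + b) is computed three ways:

- **pooled** — a from all flocks together; the headline per-class value;
- **per-survey mean ± SD** — a recomputed per survey against the constant b;
  sample SD (n − 1 divisor). A survey with no included flocks is omitted
  with a warning. A habitat unused in an otherwise non-empty survey scores
  the bound s = −1 by default; an `omit` mode drops such surveys instead,
  since published per-survey means are ambiguous on this point;
- **monthly pooled** — one value per calendar month, pooled rather than
  averaged per survey because surveys per month are unequal (1–4).

Pooled and mean-of-surveys estimators differ when surveys are unequally
sized; the package reports both and treats a ≤ 0.01 disagreement as the
expected pooled-vs-mean discrepancy, not an error.

## r-LoCoH utilization distribution

For each point the local hull is the convex hull of all points within the
fixed radius r (default 500 m, equal to the flock-discreteness distance).
Hulls are ordered by ascending area — the defining LoCoH density heuristic —
with ties broken by descending enclosed-point count, then by root index, so
the construction is fully deterministic. Walking the ordered hulls, the
running union's coverage (fraction of *all* points inside the closed union;
summing per-hull counts would double-count) is recomputed after every step,
and the p-level isopleth is the first union with coverage ≥ p. Consequences:

- achieved coverage ≥ level always; it is recorded alongside the area;
- isopleths are nested and areas non-decreasing in level by construction;
- boundary points count as covered (closed regions), which stabilises
  coverage when hulls share edges;
- duplicate coordinates are kept — repeated flocks at one field are signal —
  and degenerate hulls (points, segments) carry zero area but still cover;
- the output is invariant under point relabeling and rigid motions.

Areas are reported in hectares to 2 decimals; the 100% isopleth is
deliberately not offered (outlying exploratory points would dominate it).

## Roost-distance comparison

Per-species distance summaries report n, mean, SD and SE; SD and SE are both
printed because a field report's "±" is frequently ambiguous between them.

Repeated surveys of one area make flock distances non-independent, so the
species comparison does not use an ordinary two-sample test. Headline: a
permutation test that shuffles species labels only within each survey
stratum (preserving per-survey species counts), statistic = difference of
species means, two-sided p with the add-one correction
p = (1 + #{|t*| ≥ |t|})/(1 + n_perm) so p is never exactly zero. Groups are
taken in sorted label order, making the statistic's sign convention stable
and label-exchange antisymmetric. Companion: a fixed-effects least-squares
fit `distance ~ species + survey` (survey as a blocking factor, fit via
statsmodels OLS) reporting the species F, plus the interaction F from the
model with a species × survey term. A mixed model with a random survey
effect was deliberately not used: the stratified permutation respects the
same non-independence with assumptions that are fully explicit, and the
blocking-factor F gives the familiar scale. With a single stratum the test
reduces to the ordinary two-sample permutation test.

## Synthetic scenario

The generator emulates the targeted study design so the whole pipeline is
testable end to end:

- **Landscape** — axis-aligned rectangles with exact areas: farmland
  2,216.7 ha, marshland 38.3 ha, grassland 760.4 ha (availability
  73.5/1.3/25.2 % of 3,015.4 ha), plus water and woodland framing. The
  valley is drawn 16 km long so a weakly roost-bound species can range far.
- **Roost** — a single point on the marshy reservoir shore near the west
  end; cranes roost communally in shallow water.
- **Flock density** — f(x) ∝ w_class(x) · exp(−d(x, roost)/λ) over available
  classes, sampled by rejection with the bounding box as proposal (explicit
  failure after 10⁶ attempts). A single decay length λ per species is the
  simplest law producing the near/far species contrast.
- **Defaults** — chosen to mirror the study conditions: λ = 2.03 km
  (roost-bound species) and 6.0 km (wide-ranging species) give quadrature
  expected mean roost distances of ≈ 1.89 and ≈ 4.38 km; 24 and 32 flocks
  per survey reproduce the observed totals (288/384 over 12 surveys); the
  roost-bound species' marshland weight is 0 in November–January and 1.5 in
  February–March, giving ≈ 12 % expected marshland use in spring and ≈ 6 %
  pooled — the avoid-then-prefer seasonal switch. Flock sizes are truncated
  geometric, mean 4, cap 60.
- **Survey design** — 12 surveys over November–March (1/3/2/4/2 per month),
  fixed dates.
- **Ground truth** — expected use per class and expected mean roost distance
  by midpoint grid quadrature (step ≤ 10 m by default; tests use coarser
  steps where the integrand is smooth), cross-checked against Monte-Carlo
  sampling in the suite.

What the generator does **not** emulate: observer detection/visibility along
the transect, within-day movement, flock fission–fusion, spatial
autocorrelation beyond roost attraction, and irregular patch shapes. Passing
recovery tests therefore show the estimators recover the generative law's
signals at realistic sample sizes — not that field data meet that law.

## Numerical choices

- Reporting precision mirrors field-report convention: percentages 1
  decimal, electivity 2, areas (ha) 2, distances (km) 2.
- Habitat assignment uses closed polygons; a point on a shared boundary goes
  to the earliest polygon in map insertion order (deterministic; boundary
  points have measure zero under the generator). Maps tolerate ≤ 1 m²
  pairwise interior overlap.
- Availability percentages are rounded per class to 1 decimal; with three
  classes the rounded sum can deviate from 100.0 by up to 0.15.
- Permutation streams come from `numpy.random.default_rng(seed)`; the seed
  is a required, logged parameter everywhere randomness enters.
- Test problem sizes: recovery uses 100 replicates at 300 flocks/species and
  999 permutations; null calibration uses 500 simulations of 1,000
  permutations at 192 observations in 12 strata — sizes at which the checked
  effects are decisive while the suite stays quick.

## Known limitations

- Planar geometry only; no geodesic computation and no built-in projection.
- r-LoCoH only: no k-nearest-neighbour or adaptive-radius variants, and no
  parametric kernel density estimation.
- No selectivity indices beyond Ivlev's s, and no significance testing on s
  (monthly samples in this design are too small to support one honestly).
- The least-squares companion model treats survey as fixed; variance
  components of a random-effects formulation are not estimated.
- The coverage fraction jumps in units of 1/n, so with few points achieved
  coverage can exceed the nominal level substantially; the achieved value is
  always reported.
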