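# Methods

`mutualnet` analyses *two-layer* plant–bird mutualism networks: a
pollination layer and a seed-dispersal layer defined over the same plant
and bird communities. The object of interest is the **double mutualism** —
a (plant, bird) pair linked in *both* layers, i.e. a bird that both
pollinates a plant and disperses its seed. This note records the models,
conventions and numerical choices behind each component, and what the
synthetic-data experiments do and do not demonstrate.

## The network object and its accounting conventions

A `MutualismNetwork` holds two binary (optionally weighted) plants × birds
incidence matrices over shared, lexicographically ordered species lists.
Conventions:

- **Double mutualisms are scored as one link** in link totals and
  connectance. Connectance is `100 · L / (P · B)` with `L` the number of
  distinct linked species pairs. Because a two-layer network arguably has
  `2 · P · B` potential links, the `doubled` convention (each layer's links
  counted separately against the doubled denominator) is available as an
  explicit option; it is never the default.
- **Roles.** Every species is exactly one of: single pollination mutualist,
  single dispersal mutualist, pollinator–disperser (links in both layers
  but never to the same partner), or double mutualist (at least one
  coincident pair). Role counts partition each guild by construction.
- **Scopes.** The *overlap area* keeps the species with at least one link
  in each layer; the *double-mutualism submatrix* keeps the species
  involved in at least one coincident pair. Both operators are idempotent
  and nested (submatrix ⊆ overlap ⊆ total). A species retained by a scope
  rule keeps all its links to other retained species, even if that leaves
  it isolated in a degenerate case, so the scoped matrices are exactly the
  species-set restrictions of the original.
- Species names are trimmed, internally collapsed and matched
  case-insensitively; duplicate (layer, plant, bird) records merge by
  presence-OR and weight-mean (the intended use is pooling of repeated
  field records into one year-round qualitative network). Reported
  percentages are rounded half-away-from-zero for table parity; raw
  quotients are always retained.
- Link-kind shares are reported exactly (72.44 / 22.34 / 5.22 % on the
  built-in reconstruction); these sum to 100 but do not reproduce coarser
  published roundings such as 73/22/5.

## The built-in reconstruction

`datasets.galapagos_table1_network()` rebuilds the 108-plant × 21-bird
Galápagos archipelago network from its published *group-level* link table
(counts of pollination-only, dispersal-only and coincident links for every
plant-role × bird-role block). The table fixes totals, role counts,
connectances and layer fills exactly, but not which individual species
carry which links. The reconstruction places links deterministically along
modular "offset classes" within each block — disjoint classes for the
three link kinds — so that no unintended coincident pair arises and every
species receives links consistent with its role. Consequences:

- every group-level quantity (479 links; 25 double mutualisms; connectance
  21 % → 46 % → 62 % from total to overlap to submatrix; role counts
  2/10/7/2 birds and 61/13/7/27 plants; 48 %/12 %/18 % double-mutualist
  shares; 5.2 % double-mutualism link share) is exact, and
- the fill-preserving null distribution of the coincidence count is also
  exact (it depends only on dimensions and fills — see below), but
- placement-sensitive metrics (NODF, modularity, betweenness, degree
  correlations) describe the canonical reconstruction, not the
  field-observed matrix, and are labelled as such wherever reported.

## The double-mutualism randomization test

`dm_null_test` asks: if pollination and dispersal links were laid down
independently, how probable is a coincidence count at least as large as
observed? Both layers of the scoped matrix are randomized `n` times
(default 50,000) and `p = #{null ≥ observed}/n`, ties toward the tail; the
`(k+1)/(n+1)` estimator is also exposed for small `n`.

Null engines:

- **fill-preserving** (default): links placed uniformly at random holding
  each layer's link total fixed, margins free. Under this null the
  coincidence count of two independent uniform subsets of sizes `a` and
  `b` in `c` cells is Hypergeometric(c, a, b) — a closed form used as an
  exact oracle in the tests, never as the implementation.
- **degree-preserving**: checkerboard-swap chain holding all row and
  column degrees (10× link count attempted swaps by default).
- **Ce**: independent Bernoulli cells with `p_ij = (rowfill_i +
  colfill_j)/2`; the grand mean of the probability matrix equals the
  source fill exactly.

Cell collisions are disallowed (placements are without replacement). On
the built-in reconstruction the fill-preserving test gives p ≈ 0.132 in
the 20 × 17 overlap area and p ≈ 0.046 in the 13 × 10 submatrix at the
observed 25 coincidences — a weak positive coupling of the two functions.
Scopes: `overlap` and `dm-submatrix` mirror the two published readings;
`total` (randomize the full matrix) is provided because it is the natural
scope for simulation studies, where the full matrix's fills are fixed by
design.

## NODF nestedness and the Ce ensemble

NODF follows the overlap-and-decreasing-fill definition: a row (or
column) pair contributes `100 · shared / deg_sparser` only when the
marginal totals strictly decrease; equal totals or an empty sparser member
contribute 0. The network value is the mean over all C(R,2) + C(C,2)
pairs, in [0, 100], invariant to row/column permutation. Empty rows and
columns are kept (contributing 0) so degenerate null draws are handled
deterministically. Significance: 1000 Ce-sampled matrices, one-tailed
toward high nestedness, ties toward the tail; `z = (obs − mean)/sd`, with
`z` undefined (reported as null) when the ensemble is degenerate. The
union binary matrix (a link in either layer) is what gets nested when a
whole two-layer network is analysed.

## Modularity by simulated annealing

The two-layer network is collapsed to an undirected unipartite simple
graph (species as nodes, an edge for any link in either layer) and Newman
modularity `M = Σ_s [l_s/L − (d_s/2L)²]` is maximized by simulated
annealing in the Guimerà–Amaral style: per temperature step, `f·n²`
single-node moves (the target module may be empty, seeding splits) and
`f·n` collective moves (merge of two modules, or a random bisection);
geometric cooling (factor 0.995) from an initial temperature of `1/(2L)`
(the scale of a one-edge modularity change) until `T < T₀ · 10⁻³`. Moves
are accepted when `ΔM > 0` or with probability `exp(ΔM/T)`. The best
partition seen is returned; ties are broken first-found under the seeded
proposal order, and a run can never report less than the single-module
baseline `M = 0`. The inner loop is numba-compiled; on an 8-node graph
the search recovers the exhaustive-enumeration optimum (checked over all
4,140 partitions in the tests), and on ~130-node networks repeated seeds
agree to ~0.005.

Significance: 100 degree-preserving rewirings (double-edge swaps), each
optimized with the same schedule; `p = #{null M ≥ observed}/100`. A
Ce-style rewiring is not offered — degrees are the natural invariant for a
unipartite rewiring null.

## Betweenness, dependence, strength, linkage correlation

- **Betweenness** is Freeman-scaled shortest-path betweenness,
  `2/((n−1)(n−2))` normalization, computed on the union graph (the
  question is which species glue the two functions together); per-layer
  graphs are available. Leaves score 0, the center of a star scores 1.
- **Dependence** of plant *i* on bird *j* in one weighted layer is
  `w_ij / Σ_j' w_ij'`; rows with zero total weight stay all-zero.
  **Strength** of a bird is the sum of the plants' dependencies on it, so
  bird strengths sum exactly to the number of plants with positive
  weighted degree (and symmetrically). The two layers are never merged:
  pollen grains/mm² and viable seeds per dropping have no defensible
  exchange rate, so strength is always per-layer.
- **Strength comparisons** between role groups use a two-sided
  Mann-Whitney rank-sum statistic with a seeded label-permutation null
  (10,000 permutations by default, +1 correction); group choice (double
  mutualists vs pooled singles by default) is a parameter, and per-layer
  as well as pooled comparisons can be run.
- **Cross-layer linkage correlation**: ordinary least-squares regression
  of dispersal degree on pollination degree over the species of one guild
  present in both layers; `F = t²` of the slope with df (1, n−2). On any
  network whose overlap holds 17 birds this gives df (1, 15).

## The synthetic generator

`GeneratorConfig` → `generate_network` draws coupled two-layer networks
that emulate two drivers of island mutualism networks: *abundance-driven
degree heterogeneity* and *weak coupling between layers*.

- Species abundances are lognormal with log-sd `abundance_spread`
  (default 1.0). The pollination layer places exactly `fill_p` links with
  cell probabilities ∝ plant abundance × bird abundance, so abundant birds
  make more interactions (rank correlation between abundance and degree is
  reliably positive at spread ≥ 1).
- The dispersal layer places exactly `fill_s` links sequentially: with
  probability `coupling` onto a uniformly chosen pollination-linked pair
  (a double mutualism), otherwise onto a uniformly chosen still-empty
  cell; collisions are redrawn with bounded retries, then an error.
  Placing the coupling at link level (rather than by post-hoc swaps)
  yields the closed-form independence expectation `E[DM] = fill_p ·
  fill_s / cells` at coupling 0, used as a generator oracle.
- Weights on present links are lognormal: pollen loads with log-mean 3.0,
  log-sd 1.2 (median ≈ 20 grains/mm², heavy right tail) and seed counts
  with log-mean 0.7, log-sd 1.0 (median ≈ 2 viable seeds per dropping) —
  overdispersed positive strengths of the magnitudes seen in field data.
- Defaults: 30 plants × 15 birds, `fill_p` 120, `fill_s` 80, coupling 0.1.
  These mirror the scale and fills of the empirical overlap region (20 ×
  17, fills 124/57) and its weak observed coupling, and they give the
  coincidence count a null spread (sd ≈ 3.6) wide enough that the
  discrete one-tailed test is calibrated at the conventional 5 % level:
  the exact type-I rate at these sizes is 0.045 (0.040 with a 999-draw
  Monte-Carlo p). Very small or very dense matrices make the null
  distribution coarse and the test conservative — a property of discrete
  one-tailed tests generally, not of this implementation.
- Species left with no link in either layer (possible for low-abundance
  species) are dropped, as real interaction matrices contain only
  interacting species; fills are unaffected.

`recovery_experiment` sweeps a coupling grid: at coupling 0 the rejection
rate at α = 0.05 is ≈ 0.05 (type-I calibration); the rate rises
monotonically with coupling (up to Monte-Carlo error) and reaches ≥ 0.95
at full coupling with the default fills.

**What the synthetic experiments do not show.** The generator has no
phenology, spatial structure, trait matching, sampling effort or
detection error; its layers are conditionally independent given abundance
at coupling 0. Passing calibration and power checks therefore validates
the statistical machinery, not the ecological fidelity of any particular
field dataset.

## Problem sizes used in the shipped analyses

The test suite and the reproduction script size their simulations as
follows (the package's own choices): 50,000 randomizations for the
empirical-scale coincidence tests; 1000 Ce nulls for NODF; 100
degree-preserving nulls for modularity, optimized with a shortened
schedule (cooling 0.99, f 0.25, stop at `T₀/100`) that agrees with the
full schedule to ~0.002 on ~130-node graphs; 400–1000 replicates × 999
Monte-Carlo draws for calibration; 60–100 replicates per coupling for
power curves.

## Known limitations

- The double-mutualism test conditions on layer fills (and margins, for
  the degree-preserving engine); it does not model sampling effort.
- NODF is binary-only (no weighted NODF or temperature metric), matching
  the qualitative analysis it supports.
- Modularity is unipartite Newman modularity on the union graph;
  bipartite-specific modularity (Barber's Q) and role cartography are out
  of scope.
- Simulated annealing is stochastic: on large graphs the attained M
  varies by a few thousandths across seeds; report the seed with the
  result (the CLI does this automatically).
- The built-in reconstruction is exact only at group level; do not use
  its placement-sensitive metrics as estimates of the field network's.
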