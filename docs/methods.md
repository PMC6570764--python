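# Methods

## Model and inference

Both observation models share the low-rank structure
`p_ng = Σ_k ω_nk θ_kg`, with ω_n on the K-simplex. The multinomial
model treats each row of a count matrix as `Mult(c_n+, p_n·)` with θ_k
on the G-simplex; the Bernoulli model treats each entry of a binary
matrix as `Ber(p_ng)` with θ_kg ∈ [0, 1].

Inference is MAP EM with a per-observation latent motif indicator. For
the multinomial model the indicator attaches to each censused
individual (the topic-model construction); for the Bernoulli model it
attaches to each (sample, feature) entry, `z_ng ~ Cat(ω_n·)`,
`m_ng | z_ng = k ~ Ber(θ_kg)`, whose marginal is exactly the low-rank
`p_ng`. Both E-steps reduce to matrix products, so a sweep is
O(N·G·K). The M-steps are prior-smoothed weighted proportions
(multinomial θ and ω) and prior-smoothed weighted Bernoulli means
(Bernoulli θ). The EM objective — log likelihood (multinomial
coefficient dropped; it is constant on fixed data) plus log priors — is
non-decreasing by the standard minorization argument, and the test
suite asserts this on every fit it makes.

Numerical choices: implied probabilities are clipped to
[1e-12, 1 − 1e-12] inside E-steps and logs; convergence is declared
when the relative objective change falls below `tol` (default 1e-8,
cap 1000 sweeps); initial ω rows are Dirichlet(1) draws, initial θ rows
are normalized Gamma(1) draws (multinomial) or Uniform(0.1, 0.9)
entries (Bernoulli), all from the seeded generator. Likelihood
evaluation of an exact zero probability against a positive observation
returns −inf rather than raising, so degenerate candidate fits can
still be ranked.

### Priors

"Non-informative" is implemented literally: symmetric Dirichlet(1) on
ω rows and multinomial θ rows, Beta(1, 1) on Bernoulli θ entries, so
MAP EM defaults to maximum likelihood. Concentrations are exposed
(`prior_omega`, `prior_theta`); values above 1 give additive smoothing
and keep EM monotone. Values below 1 are accepted but push mass to the
simplex boundary and are clipped at 1e-12; they are not recommended.

### Approximate Bayes factor

Fits are ranked by a BIC-style approximation to the log Bayes factor
against the K = 1 fit of the same data:

    log BF(K) = [obj(K) − obj(1)] − ½ · Δparams · log(n_obs)

where obj is the MAP objective, Δparams is the difference in free
parameters (multinomial: N(K−1) + K(G−1) vs G−1; Bernoulli:
N(K−1) + K·G vs G; partition-constrained fits count only θ because ω
is preset), and n_obs is the total individual count (multinomial) or
N·G Bernoulli trials. The K = 1 objective has a closed form (prior-
smoothed column proportions/means). By construction log BF(1) = 0.
This quantity is used for exactly one purpose — ranking fits of
identical data: restarts, K values, constrained competitors, and
observed vs permuted matrices. Its absolute value is an approximation
and is not comparable across datasets or with other software's Bayes
factors.

### Restarts, label switching, constrained competitors

`multistart_fit` runs EM from `n_starts` child seeds (master + index)
and keeps the highest log BF; the procedure is deterministic given the
master seed. Label switching between fits is resolved by maximising the
summed Pearson correlation of matched θ rows over permutations, solved
exactly with the Hungarian assignment (ties resolve deterministically).
Partition-constrained competitor fits — ω preset to one-hot labels,
e.g. a fixed elevational split — estimate θ in closed form and report
the same log BF approximation so free and preset partitions can be
compared directly.

## Geographic stage

Range grids are binary rasters on a shared lon/lat extent and square
resolution, stored with row 0 at the northern edge; vectorization is
row-major from the north-west corner, centre-registered, longitude
east-positive. This convention is fixed so cell (column) identifiers
are reproducible across runs and documented in file headers (ESRI
ASCII grids, read and written natively; the raster formats carry
their own geometry so round trips are exact).

The global presence matrix keeps a cell when its land fraction is
≥ 0.10 AND at least 3 ranges overlap it — both thresholds read as
"at least", both configurable. Assemblage dispersion fields count, per
cell, how many of a community's species have ranges covering it;
stacking the vectorized fields gives the sites × cells count matrix
fed to the multinomial model. Species-name matching normalizes case
and underscore/whitespace and then requires exact equality; fuzzy
joins are deliberately not attempted because they corrupt matrices
silently.

## Phylogenetic stage

The tree must be rooted, ultrametric (tip-depth spread within 1e-6
relative tolerance — violations are rejected with the offending tips
listed, not auto-corrected), with branch lengths in Myr. Cutting at T
defines one clade per edge whose age interval covers T, under the
convention that a node exactly at age T belongs with the edge above
it: an edge is a lineage when `child_age ≤ T < parent_age`, the root's
parent age taken as infinite, with a 1e-9·(root age) fuzz absorbing
floating-point error in node ages. Hence T = 0 is the identity map,
T ≥ root age is a single clade, and slices are nested (clades at a
deeper T are unions of clades at a shallower one). Clade ids are
`T{T}_{lexicographically smallest member tip}`. Collapsing sums member
species columns; row totals are conserved exactly in integer
arithmetic.

## Null models

Definitions follow the standard community-ecology conventions the
method names denote: `frequency` shuffles within columns (preserves
species occurrence multisets), `richness` shuffles within rows
(preserves site multisets), and the two swap methods perform 2×2
checkerboard submatrix moves, which on binary matrices preserve both
marginals exactly. `trialswap` counts attempted moves, `independentswap`
successful ones; the default effort is 10× the number of occupied
cells, and a matrix with no checkerboard unit is returned unchanged
with a warning. Whether counts are binarized before permuting is a
logged option (`binarize`), since either convention is defensible for
abundance surveys.

The significance procedure refits the model at fixed K on each
permuted matrix and reports (a) the add-one empirical tail probability
of the worst observed log BF within the null distribution and (b) a
Mann–Whitney U test (rank-sum with tie correction, alternative:
observed greater) treating the observed list — typically the
multistart spread — as a sample. With a single observed value the U
test degenerates and the empirical tail is the meaningful number; the
report says which inputs were used.

A calibration caveat discovered while validating the procedure: on
data with *no* motif structure (K = 1 generative model), the richness
null itself destroys the shared column profile that the K = 1 model
explains, so null fits score *higher* than the observed fit — the
comparison is anti-conservative in reverse and cannot be used as a
negative control. The frequency null preserves column profiles and is
calibrated: on unstructured data the observed log BF falls inside the
frequency-null range in most seeds. The calibration checks therefore
use frequency nulls, while the positive-control (blocked data)
comparison uses richness nulls, where permutation genuinely destroys
the block structure.

## Synthetic study conditions

The generators are exact samplers of the stated models, and their
defaults are the conditions every recovery and significance number in
the tests and `scripts/acceptance.py` refers to:

* `simulate_gom` — ω rows ~ Dirichlet(0.3) (moderately concentrated
  memberships: most sites dominated by one motif with a mixing
  minority, as in real elevational gradients); θ rows are the convex
  blend `(1 − s)·baseline + s·private-block` with separation s = 0.8
  by default (strong but not disjoint profiles); census depth 500–1000
  individuals per site, matching the order of magnitude of a thorough
  5-ha survey. Bernoulli θ blends a Uniform(0.15, 0.5) baseline with
  0.9/0.02 block occupancy. All-absent Bernoulli rows are resampled.
* `simulate_ranges` — rectangular ranges on a small lon/lat grid, with
  an optional two-band layout confining two species pools to the
  northern ("temperate", high-elevation sites) and southern
  ("tropical", low-elevation sites) halves, giving dispersion fields a
  known K = 2 truth; site regions split east/west at the grid midline.
* `simulate_timetree` — forward pure-birth simulation rescaled so the
  root sits exactly at the requested age.

What these fixtures do **not** emulate: spatially autocorrelated or
climate-shaped range boundaries, phylogenetic signal in the θ profiles,
detection error in censuses, and the strong column dependence of real
co-occurrence data. Passing recovery tests therefore demonstrates the
estimator is correct *under its own model*, not that real assemblages
satisfy that model — on real data the Dirichlet independence
assumption across columns is known to be wrong (species are related
and ranges are spatially coherent), which is precisely why Bayes
factors are treated as rankings rather than evidence magnitudes.

## Problem sizes

The validation suite runs at deliberately modest scales chosen to
exercise every code path at survey-like dimensions: recovery at
N = 200 sites × G = 100 species, K = 3, depth 1000, 10 seeds × 20
restarts; null ensembles of 50 replicates (positive control) and
10 × 20 replicates (calibration); contract checks over 100 randomized
fits. Full-scale analyses (e.g. a 17,441 × 9,518 global presence
matrix, thousands of restarts, 1000-replicate ensembles) use the same
code paths and scale linearly in N·G·K per sweep.

## Known limitations

* The Bayes-factor approximation is BIC-like; it will not numerically
  match marginal-likelihood estimates from other software, and should
  only ever rank fits of the same matrix.
* EM finds local optima; multistart mitigates but does not guarantee
  the global MAP, which is why restart counts are exposed everywhere.
* The model ignores spatial adjacency of map cells and phylogenetic
  relatedness of species; the time-slice stage captures relatedness
  only coarsely.
* Swap nulls use a burn-in heuristic (10× occupied cells); mixing on
  very large sparse matrices may need more swaps, and only binary
  matrices retain both marginals under swaps.
* Rasterization of range polygons is upstream of this package; grids
  are consumed as given (ESRI ASCII), with no projection support
  beyond geographic lon/lat.
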