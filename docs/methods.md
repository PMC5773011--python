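# Methods

## The model

The musculoskeletal system is reduced to a hypergraph: bones (plus the
ligaments and tendons that serve as attachment points) are nodes, and
each muscle is a hyperedge joining every bone it originates from or
inserts on.  The whole structure is a bones × muscles incidence matrix
`C` with `C[i, j] = 1` iff bone *i* is an attachment of muscle *j*.
The hyperedge degree *k* of a muscle is the number of bones it touches.
Two one-mode projections summarize the structure: the bone-centric
matrix counts muscles shared by each bone pair (`C Cᵀ`, diagonal
zeroed) and the muscle-centric matrix counts bones shared by each
muscle pair (`Cᵀ C`, diagonal zeroed).  The projections are defined by
these shared-counterpart semantics; note that matrix-product notation
for them depends on the orientation chosen for `C`, which is a common
source of transposition slips in the literature.

Analysis is intended for one body half (each motor cortex controls the
contralateral side); the parser accepts a `side` column and can filter,
but treats input as already one-sided by default.

### Spring–mass perturbation and the impact score

Bones are unit point masses at estimated 3D centre-of-mass positions;
a muscle of degree *k* ≥ 2 becomes the complete set of *k(k−1)/2*
damped springs among its bones, each with strength `1/(k−1)` (times an
optional per-muscle multiplier), so every muscle exerts the same total
restoring force budget regardless of degree.  Strengths accumulate on
bone pairs shared by several muscles.  Rest lengths equal initial
distances: the resting body is at equilibrium.  The equation of motion
for node *i* is

    m_i r̈_i = Σ_j S_ij û_ij (x_ij − ‖l_ij‖) − β ṙ_i

with `l_ij = r_i − r_j`, rest length `x_ij`, damping β = 1, and the
sign fixed so stretched springs attract; a unit test enforces the
restoring convention.

To perturb a muscle without privileging any anatomical direction, all
of its member bones are displaced by a constant `d` into a fourth
spatial dimension and clamped there; boundary bones flagged *fixed*
(midline/periphery in the real anatomy, the axis ends in the synthetic
body) are clamped at rest unless they are members, in which case the
membership clamp wins.  The **impact score** is the total distance
moved by all nodes: in the dynamic mode the dt-weighted time-quadrature
of summed displacement norms from perturbation onset until the free
nodes come to rest (length × time units); in the steady-state mode the
summed equilibrium displacement norms (length units).  Clamped member
bones are included by default (they did move); a flag excludes them,
and a `normalize` flag divides by the node count (total vs mean differ
by a constant that cancels in every downstream correlation).  An
orthogonal-3D variant perturbs along x, y and z separately and reports
the vector-sum magnitude of the three steady-state impacts.

**Numerical choices.**  Dynamics use semi-implicit Euler (default
dt = 0.01, termination when the fastest free node stays below 1e−6
speed for 10 consecutive steps, or at t = 500).  The steady state is
found by L-BFGS energy minimization followed by Levenberg-damped
Newton steps on the force residual using the analytic tangent
stiffness.  The default residual tolerance is 1e−4 (max per-node force
norm); well-constrained fixtures converge to ~1e−12, but springs at
their rest length have zero transverse stiffness, so chains of
unstressed springs act as mechanisms whose restoring forces are cubic
in the displacement — both dynamic relaxation (algebraic, ~t^−1/2) and
any Newton-type solver resolve those modes only to finite precision.
The solver-agreement tests therefore use taut fixtures in which every
spring is stretched at the perturbed equilibrium and all modes are
exponentially stable.  The perturbation magnitude d = 1 body-coordinate
unit is a pinned configuration value (the 4D response is nonlinear in
d, so impact scores are only comparable at a common d).

### Null ensembles and impact deviation

Raw impact is dominated by degree, so each muscle is referenced against
degree-matched muscles in an ensemble of null hypergraphs.  Variants:

* **triad_rewire** (default): muscles are first partitioned into groups
  of roughly three topologically related muscles, and attachments are
  shuffled only within groups — a data-driven way of perturbing wiring
  locally while preserving every muscle's degree.  The triad
  partitioner greedily maximizes modularity on the
  resolution-adjusted muscle-centric matrix minus an equal-size
  penalty Σ_c (size_c − N/K)²; because that penalty blocks single
  moves between balanced groups, converged sweeps alternate with
  size-neutral pairwise exchanges, and sizes are forced into [2, 5]
  post hoc.
* **category_rewire**: shuffling within homunculus categories.
* **free_rewire**: shuffling among all muscles.
* **random**: attachments placed uniformly at random, preserving only
  the total attachment count.

Rewiring uses attachment-endpoint double swaps with duplicate
rejection, 10 × (group attachments) attempts per replicate; degree
preservation is exact and audited in tests.

The **impact deviation** is the z-score-like quantity
(impact − null mean)/null std with null statistics pooled per exact
hyperedge degree across the ensemble (degrees with fewer than two null
observations widen symmetrically to neighbouring degrees; logged per
muscle).  A CI-referenced variant — distance to the nearest bound of
the normal-theory 95% interval divided by std, zero inside — is
available behind a flag; the plain z-score is primary because the
CI-referenced form is ill-defined inside the interval.  |z| > 1.96
flags a muscle as significantly more/less impactful than expected.
The **deviation ratio** of a homunculus category is the fraction of
its muscles with positive deviation.

### Communities and the homunculus

Community detection maximizes unnormalized modularity
Q = Σ_ij (B − γP)_ij δ(g_i, g_j) via the resolution-adjusted matrix
B′ = B − γ kkᵀ/Σk (k the strength vector) and a locally greedy,
Louvain-like algorithm (greedy node moves with seeded random visit
order, then aggregation, repeated).  Because runs are stochastic, a
consensus partition is extracted from many runs by thresholding the
co-assignment matrix at its permutation-null expectation and
re-clustering until all runs agree (Lancichinetti–Fortunato-style).
Q is reported unnormalized (only the argmax matters), so Q values are
not comparable across networks.  The resolution γ is a configuration
value — chosen in the original analysis so the community count matches
the 22 homunculus categories — and a sweep utility re-derives it on new
data.  Partition similarity uses the z-score of the Rand pair count
under the exact hypergeometric permutation model (mean and variance
from the two group-size profiles).

### Linear ordering by classical MDS

The muscle-centric matrix is binarized (edge iff weight > threshold,
default 0), hop-count shortest paths form a distance matrix with
unreachable pairs coded 0 — the published convention, kept as the
faithful default even though it biases classical MDS; a
largest-connected-component alternative is provided — and classical
(Torgerson) MDS of that matrix yields the first principal coordinate
per muscle (double-centre −½ J D² J, leading eigenvector scaled by
√eigenvalue; sign arbitrary, so reported correlations are sign-free).
A weighted variant uses edge length 1/weight with Dijkstra paths and
no threshold.  Short-/long-connection subnetworks split edges at the
mean Euclidean distance between muscle centroids (centroid = mean of
member-bone coordinates; ties go to "short", so the two edge sets
partition the full set).

### Regressions

All reported fits are simple linear regressions by iteratively
reweighted least squares with the bisquare influence function at the
conventional tuning constant 4.685; observation weights (the number of
muscles behind an aggregated point) multiply the robust weights.  R²
is computed on the final weighted fit (weighted SSE/SST — robust R²
definitions vary, so this is stated explicitly), F = R²/(1−R²)·(n−2)
with df = (1, n−2), and p is the F tail probability.  The headline
analyses: recovery weeks ~ mean group deviation (group-size weighted),
mean group deviation ~ motor-strip activation volume, deviation ratio
~ medial-to-lateral category index, and MDS coordinate ~ category id
across all muscles.  The printed recovery, volume and category tables
ship verbatim as package data; the mapping of composite injury groups
to member muscles is not printed anywhere and must be supplied by the
user (the synthetic generator produces its own grouping).

## The synthetic body

The generator emulates the statistical structure the analysis relies
on, and nothing anatomical beyond it: bones at unit spacing along one
body axis with Gaussian 3D jitter (sd 0.3); hyperedge degrees with a
point mass at 2 (60% of muscles — most muscles span a single joint)
and a zeta-like tail p(k) ∝ k^−3 for 3 ≤ k ≤ 10; attachments drawn
with affinity exp(−axis distance/2) around a random anchor, which
plants spatially localized hyperedges and hence community structure;
contiguous axis intervals as category labels (homunculus stand-in);
and ~10% of bones, split between the two axis ends, flagged fixed.
A single seed determines every output byte-for-byte.  Clinical-style
tables are drawn as recovery = effect·(mean group deviation) + noise
(shifted to be non-negative) with volumes on the same linear model for
a subset of groups, so the regression layer's parameter recovery can be
checked at known effect sizes.

What passing tests on this generator do **not** show: anything about
absolute impact magnitudes in a real body, about anatomically
plausible rewirings, or about the specific published network — those
statistics (173 bones/270 muscles, 22 communities at γ = 4.3, the
printed R² values) are properties of the deposited supplementary
tables, which the loaders accept but the package does not ship.

## Problem sizes

The demo/acceptance scale is a 30-bone/40-muscle body with a 30-replicate
triad-rewired ensemble and 50-run consensus clustering — chosen as the
package's standard end-to-end example so the full pipeline completes in
about a minute on one CPU.  All counts are configuration values; the
published analysis scale (100 null hypergraphs, 100 modularity runs) is
the default in `RunConfig`.

## Known limitations

* No joints, collision handling, or range-of-motion constraints: bones
  are free points and can adopt anatomically impossible configurations.
* No muscle-fiber subcompartments; a muscle is one hyperedge.
* The 0-for-disconnected distance convention compresses unreachable
  pairs toward the origin in MDS; prefer the LCC mode when faithfulness
  to the published pipeline is not required.
* Mechanism modes bound the achievable solver precision (see above);
  impact scores are reproducible to far better than the statistical
  tolerances used anywhere downstream, but not to machine precision on
  generic networks.
* Null rewiring ignores anatomical plausibility by design.
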