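# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `convsearch`, in the package's own terms.

## Phenotypes as directions

Species are points in a p-dimensional trait space; the test works with
their *directions* from the origin.  For geometric-morphometric PC
scores the origin is the consensus shape, so the angle between two
species' vectors measures whether they deviate from the consensus the
same way.  The angle is scale-invariant (θ(cA, B) = θ(A, B) for c > 0)
and reflection maps θ to 180° − θ.  Zero-norm vectors have no direction
and raise an error rather than propagating NaNs; an exact hit on the
consensus shape is pathological in real data.  The arccos argument is
clamped to [−1, 1]; angle resolution near cosines of ±1 is of order
√machine-epsilon (~10⁻⁶ degrees), which the unit tests treat as exact.

## Phylogenetic ridge regression

Each branch j carries a rate vector β_j (trait units per time) such
that every tip satisfies y_tip = y_root + Σ β_j l_j over its root-to-tip
path.  Per variable, β minimizes

‖y − Xβ‖² + λ Σ_j l_j β_j²,

where X is the path design (X[i, j] = l_j if branch j is on tip i's
path).  The penalty weight l_j prices the squared phenotypic *change*
across a branch divided by its duration — the scaling under which BM
increments accumulate — so a short branch is neither a free sink for
jumps nor priced out entirely.  Substituting γ_j = β_j√l_j gives an
ordinary ridge problem on a √l design, solved through one SVD per tree
(all variables and all λ values reuse it).  Useful consequences:

* λ → 0 interpolates the tips, and the ancestral states then coincide
  with the BM maximum-likelihood (independent-contrasts) reconstruction;
* the path-sum identity state(n) − state(parent) = β_n l_n holds exactly
  for every fit, by construction;
* zero-length branches get β = 0 (no time, no change).

The root is the BM generalized-least-squares root (phylogenetically
weighted tip mean), computed from the shared-path covariance matrix with
a 10⁻¹⁰-scale diagonal jitter for safety.

**λ selection ("auto").** Per variable, λ minimizes 5-fold
cross-validated squared tip prediction error on a 9-point log grid over
[10⁻⁶, 10⁴], refined by a bounded scalar search (xatol 0.05 in log10);
fold assignment comes from a fixed fold seed, so the choice is
deterministic.  For noise-free BM-like data this criterion selects very
small λ (the BM interpolant is the best cross-tip predictor), while
phylogenetically unstructured data drives λ toward the upper bound.
Quantities built on ancestral states (θ_ace) are mildly sensitive to
this rule; rank-based p-values of the tip-angle test are not.

**Fossil constraints.** A constrained node's clade is re-fit as a
subtree whose root is pinned to the supplied vector, and the remaining
tree is fit with the node standing in as a pseudo-tip carrying that
vector.  The constrained values are returned verbatim; the path-sum
identity holds within each part but not across the constrained branch
(the pinned value takes precedence over the ridge prediction there).
Nested constraints are rejected.

## The convergence tests

**Clade mode.** Observed statistic θ_real/d (mean cross-clade tip angle
over the patristic distance between the two mrcas) ranked against 1000
random tip-pair draws (tip angle over the distance between the tips'
immediate ancestors; zero-distance draws — sister tips or coincident
ancestors through zero-length branches — are redrawn).  The
parallel-trajectory statistic is (θ_real + θ_ace)/d against the null
(θ_random + θ_ace of the tips' ancestors)/d, the whole sum divided, so
statistic and null share a scale.  P-values are ECDF fractions of draws
at or below the observed value; the smallest reportable value is
1/n_null and a statistic below every draw is stored as p = 0 and printed
as "<1/n".  One shared null serves all pairs of a search.

The automatic mode enumerates unordered internal-node pairs with
ancestor-disjoint clades of at least `min_clade_size` tips (default 5)
at least ⌈ntips/10⌉ edges apart; a patristic-distance threshold can
replace the edge-count rule.  Node distance is counted as edges on the
mrca-to-mrca path — an unambiguous convention; exclusive "nodes between"
counting differs by one and is absorbed by the threshold parameter,
which is configurable.  No multiple-testing correction is applied across
candidate pairs (a Bonferroni option exists, off by default): the test
is reported per pair, overlapping significant pairs are collapsed to
their most inclusive representative per region (phenotypes at
neighboring nodes are strongly autocorrelated, so significant pairs
cluster), and representatives are ranked by dispersion — the mean
distance of species from their own clade centroid — tightest first,
since convergence toward an attractor keeps species close to their
centroids.  Maximum clade size is unbounded; the ancestor-disjointness
rule is the only upper constraint.

The tip-angle p-value is *conservative* for clade pairs under BM (the
mean cross-clade angle and the mrca divisor are not exchangeable with
single tip-pair draws); exact uniformity holds when the observed
statistic is itself a random tip pair, which is what the calibration
test asserts.  The family-wise rate over all candidate pairs is
therefore meaningful only per region, and detections are scored at the
region of interest.

**State mode.** Within one state: mean pairwise angle, and mean of
angle/patristic-tip-distance; between two states: the same over cross
pairs.  The null permutes the complete label vector (background
included) across all tips — the question is whether the labeled species
are more mutually similar than a random set of the same size.  Both raw
and time-normalized p-values are reported; they can disagree, and the
package's significance convention (used by the error-rate suites) is
the time-normalized one, which accounts for phylogenetic separation.
Tip pairs at zero patristic distance are excluded from the
time-normalized mean with a warning.

## Simulation framework

All simulators are pure functions of (inputs, seed); suites spawn one
child generator per replicate from the master seed and log it.

* **Trees.** Forward-time birth–death (defaults birth 0.5, death 0.2),
  grown until `min_tips` lineages are simultaneously alive, extinct
  lineages kept as fossil tips (non-ultrametric, like paleontological
  trees), terminal branches extended by one extra waiting time so no
  tip ends exactly at an event.  Validation trees grow past 80 extant
  species and end up at roughly 130–250 tips including fossils.
* **Traits.** BM with σ² = 1 per variable (3 variables in the clade and
  state experiments); the kappa/delta/lambda transforms rescale branch
  lengths (kappa: l^κ; delta: depths d → d^δ rescaled to the original
  height; lambda: internal depths shrunk by λ with tip depths fixed —
  the covariance transform); trend multiplies each branch by
  1 + a·(mid-depth), floored at a small epsilon; drift adds ds·l to the
  mean along every branch and equals BM draw-for-draw at ds = 0.
* **Planted clades.** A source clade sized 1/10–1/4 of the tips with
  mrca no deeper than 80% of tree height is duplicated; the copy loses
  2 random tips, has half its tips transposed and half its branch
  lengths perturbed by U(0.5, 1.5), and is grafted at an internal node
  at least ⌈ntips/10⌉ edges away (or exactly 3 for the close-pair
  design): the branch above the target is bisected, the copy hangs from
  the midpoint on a positive stub and is rescaled so its deepest tip
  matches the target clade's deepest tip.  Both copies' species then
  get phenotypes jittered multiplicatively around f·(per-variable
  column maxima of the original data), f ~ U(0.5, 2) drawn once per
  simulation, with relative spread 2% — tight clusters whose angular
  dispersion scales with the cluster center and is therefore nearly
  independent of f.  The matched type-I condition applies the same
  structural edits but simulates a fresh BM phenotype on the final
  tree.
* **Planted states.** 3 to ⌈ntips/10⌉ random tips per state get the
  same jittered cluster phenotypes in place; the second state's spread
  is doubled; background tips are untouched.
* **26-tip three-lineage design.** Pure-birth trees of exactly 26 tips;
  10 BM traits with broken-stick variances v_i = (1/10)Σ_{j≥i} 1/j;
  2–10 traits retained per replicate; three tips pairwise ≥3 nodes
  apart tested as one state.  Under the convergent condition each
  selected lineage follows an OU pull toward θ = 1.25 × the per-trait
  BM maxima with strength α ~ U(1, 50), acting over the lineage's
  history since the three tips' most recent common ancestor, with
  stationary-scaled OU noise.  (Pulling only the terminal branch was
  tried first and under-converges badly on short terminal branches.)

**Scoring.** A clade-mode detection (or false positive) is a significant
pair whose mrcas both lie within 2 edges of the planted mrcas;
identification accuracy compares the top-ranked representative pair to
the truth the same way; species recovery is the fraction of planted
tips inside the union of the detected clades.  The three-node design is
scored with the planted pair specified explicitly, because a pair 3
nodes apart is below the automatic mode's distance threshold and cannot
be enumerated.  Error-rate tables carry Clopper–Pearson binomial
confidence intervals.

**Problem sizes.** The shipped test suite and acceptance script run the
clade experiments at 25–100 replicates, states at 50–100, and the
26-tip experiments at 200–1000 replicates; these counts give 99%
binomial bands a few percentage points wide while keeping a full run in
minutes on one core.

## What the simulations do and do not show

The generators reproduce the validation conditions: non-ultrametric
trees, uncorrelated BM variables, and convergence implanted as tight
phenotype clusters near the edge of the data cloud.  Real
morphometric data differ in ways the simulations do not model:
correlated PC axes with strongly decreasing variances, measurement
error, phenotypes far from multivariate normal, and convergent taxa
that are loose clusters rather than near-copies.  Passing error-rate
checks therefore certify the machinery and its calibration under the
stated conditions, not performance guarantees on any particular
empirical dataset.  Two further caveats: the tip-pair null is itself
built from the data at hand, so very large convergent clades pollute
its low tail and cap attainable power (noticeable when a clade pair
holds more than ~a quarter of all tips); and the parallel-trajectory
test inherits ancestral-state error at clade boundaries, making it the
less powerful of the two tests when clade stems are short.

## Known limitations

* Polytomies are rejected (the ridge design assumes bifurcation); a
  zero-length random resolution helper exists in the newick reader but
  is off by default.
* Node constraints must not be nested.
* The state mode does not exclude within-subclade pairs, so a
  phylogenetically clustered "state" partly re-tests clade structure;
  users with clustered states should prefer the clade mode.
* The λ rule is a pragmatic cross-validation criterion; alternatives
  change θ_ace by a few degrees on short-stemmed clades.
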