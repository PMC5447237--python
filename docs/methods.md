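# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `cytomark`, at the level of detail a
user needs to judge what the package's tests do and do not establish.

## The annotation model

The pipeline assumes that on the arcsinh scale each marker's intensity
distribution across all cells is approximately a two-component Gaussian
mixture — a "low" (unexpressed) and a "high" (expressed) mode — and that a
cell type is a binary pattern over markers.  Prior knowledge enters as a
sign table `s(c, m) ∈ {+1, −1, 0}`: type `c` requires marker `m` high, low,
or places no constraint.

**Marker models.**  Each marker column gets a univariate two-component
mixture fit by EM (scikit-learn `GaussianMixture`, k-means initialization,
10 restarts, fixed seed).  Two EM settings differ from scikit-learn
defaults and matter:

* `tol = 1e-7`, `max_iter = 1000`.  The default `tol = 1e-3` terminates EM
  after a handful of iterations when one mode is rare (weight ≲ 0.1),
  leaving the rare mode's mean biased by several tenths.  The package's
  parameter-recovery guarantee (means within 0.1, weights within 0.05 at
  n = 20,000) holds down to minority weights of ~0.08 with the tighter
  tolerance.
* A fit is *flagged* as degenerate — and scoring with that marker refuses
  to run — when a component weight drops below `1e-3`, the means coincide
  (closer than `1e-6`), no posterior crossover exists between the means, or
  Ashman's bimodality index `D = √2·(μ_high − μ_low)/√(σ_low² + σ_high²)`
  falls below `1.9`.  The last criterion is what actually catches unimodal
  columns: EM fit to a single Gaussian converges to two strongly
  overlapping components (measured `D ≈ 1.5–1.7`) that pass the weight and
  separation floors, while a genuinely bimodal column at two-sigma mode
  separation measures `D ≳ 2.1`.  The floor is configurable
  (`bimodality_floor=0` disables it) because dim-vs-negative markers in
  real panels can sit near the boundary.
* One failure mode is *not* flagged reliably: a marker whose minority mode
  holds ≲ 1% of events.  EM then tends to split the majority mode instead
  of finding the rare one, and no diagnostic on the fitted parameters can
  tell this from a dim doublet.  Panels should avoid markers expressed only
  on ultra-rare populations, or the affected marker should be dropped from
  the table.

**The logistic posterior.**  The exact mixture posterior for the high state
is not monotone in intensity when the component variances differ (far into
the wide component's tail, the wide component dominates again).  The
package therefore scores with a logistic approximation `P̃(+1|w) =
expit(b(w − a))`: `a` solves `π_h N(a; μ_h, σ_h²) = π_l N(a; μ_l, σ_l²)` by
root-bracketing on the log-density difference (tolerance 1e-12, bracketed
on `[μ_l, μ_h]`, where the difference always changes sign for a usable
fit), and `b = (a − μ_l)/σ_l² − (a − μ_h)/σ_h²`, which is 4× the exact
posterior's slope at `a` — a logistic with rate `r` has slope `r/4` at its
midpoint, so the approximation matches the exact posterior in value (½) and
derivative at the critical point.  When the variances are equal the exact
posterior *is* this logistic, for any component weights; the approximation
is then exact everywhere (verified to 1e-9 in the tests).

**Scores.**  `f(w, c) = min` of the state posteriors over the markers the
table specifies for `c` — a conjunction: one violated requirement vetoes the
type.  `f(w, unknown) = 1 − max_c f(w, c)`.  Scores live in [0, 1] and the
unknown column is the exact complement of the best type score.

## Landmarks

Events with a type score above ½ join that type's subset (if two types
exceed ½ — possible with nested requirement sets — the argmax wins, so the
subsets stay disjoint and landmark labels unambiguous; the overlap count is
logged).  Events whose *unknown* score exceeds ½ form the unknown pool.
Events exceeding no threshold are left out of landmark generation entirely
and are only classified later by the walker — at four-sigma mode separation
with 4–5 specified markers per type, roughly 10% of genuine events have one
borderline marker and land in the unknown pool or unassigned remainder,
which is why pure score-argmax classification (the first baseline)
plateaus around 90% here.

Each subset is clustered by community detection (Leiden refinement of
Louvain greedy modularity maximization, seeded, iterated to convergence;
igraph/leidenalg) on a k-nearest-neighbour graph (k = 30, Euclidean, ties
broken by index) whose edge weights are the Jaccard similarity of the two
endpoints' neighbour sets (self excluded); zero-overlap edges are dropped.
Every community with at least `min_cluster_size = 10` members contributes
one landmark: its coordinate mean, labelled with the subset's type, or
`unknown:1`, `unknown:2`, … (numbered by decreasing size) for the unknown
pool.  Smaller communities and subsets are dropped with a warning — tiny
communities yield noisy centres and spurious unknown clusters.

Modularity maximization on the kNN graph of a *homogeneous* point cloud
legitimately splits it into several communities (there is no "one blob, one
community" guarantee), so types are typically represented by several
landmarks.  This is harmless: classification aggregates per class, not per
landmark.  The landmark CSV (label, member count, coordinates) is the
reusable fingerprint of the experiment.

## Random-walker classification

The classification graph is a k-nearest-neighbour graph (k = 10 by default)
over the union of the sample's events and the landmark points, symmetrized
by edge union.  Edge weights default to a Gaussian kernel
`exp(−d²/σ²)` with `σ` equal to the mean distance to the k-th neighbour
over all points, so nearer neighbours dominate the walk; `--unweighted`
gives unit weights.  Every connected component must contain a landmark —
a component without one is an error (it signals k too small or a dropped
population), never a silent "unknown".

The probability that a walker starting at node `x` first reaches a landmark
of class `c` satisfies the discrete Laplace equation: harmonic at interior
nodes, 1 at class-`c` landmarks, 0 at other landmarks.  With graph
Laplacian blocks this is `L_UU P_U = W_UB B_c`, one sparse SPD system per
class sharing a single LU factorization (`scipy.sparse.linalg.splu`;
problem sizes here are ≤ ~2×10⁴ interior nodes, well inside direct-solver
range).  After solving, the weighted-neighbour-average property is verified
at every interior node to 1e-8; solver-level negative noise is clipped to
[0, 1] afterwards.  Because the boundary indicator columns sum to one at
every landmark, linearity makes each row of the solution sum to one
(asserted to 1e-6), and the maximum principle keeps interior values
strictly inside (0, 1).  Labels are the argmax class (ties to the lowest
class index, logged); unknown clusters keep their separate identities in
the output and are only merged to a single "unknown" class for metric
computation against references, which carry no sub-cluster identities.

For multi-replicate experiments, marker models and landmarks come from the
pooled matrix; each replicate is then classified independently on its own
walk graph against the shared landmarks, and frequencies are label counts
over the declared class universe (absent classes report 0).

## Evaluation

Frequency agreement: maximum absolute error, Canberra distance
(`Σ|h₁−h₂|/(h₁+h₂)`, convention 0/0 = 0; each class contributes ≤ 1, so
rare populations weigh as much as abundant ones) and intersection distance
(`1 − Σ min(h₁, h₂)`, equal to half the L1 distance for normalized
histograms — asserted as an internal consistency check).  Per-class
precision (purity), recall (yield) and F1 from the confusion matrix; a
class never predicted or never present gets F1 = 0 and a flag.  Silhouette
coefficients (scikit-learn, Euclidean, optional seeded subsampling) measure
cluster tightness.  Per-type Pearson correlations across replicates compare
estimated and reference frequency series; zero-variance series yield a
missing value, never an imputed 0, since averaging imputed zeros would
silently deflate the summary.  Stratified folds preserve class proportions
(classes smaller than the fold count are spread round-robin and flagged).
Reference labels outside the classifier's known universe ("ungated", novel
population names) are mapped to the unknown class before any metric.

## The synthetic generator

`synthetic` generates what the model assumes, with known ground truth:
every marker bimodal on the transformed scale (`μ_low = 0`, `μ_high = 4`,
`σ = 1`; the `hard` variant doubles σ for two-sigma separation), every type
a fixed binary profile.  Markers a type's table row ignores still have a
definite state in its cells, fixed once per (type, marker) — resampling per
event would smear types into incoherent clouds, unlike real populations.
Replicate compositions are either fixed or Dirichlet-perturbed around the
base frequencies (`freq_concentration` ≈ 100 gives realistic
sample-to-sample variation of a few percentage points absolute).

The canonical benchmark: 8 populations over a 12-marker panel (CD4/CD8
T cells, B cells, NK, classical/non-classical monocytes, basophils, and
pDC as the rare population at 0.5%), plus a CD3+CD19+ B/T-mixed novel
population at 3% that is deliberately absent from the table.  The novel
profile contradicts at least one specified marker of every table row, so
its true score is below ½ for every type — it must surface as unknown
clusters.  Explicit full profiles keep the types mutually distinguishable
(e.g. non-classical monocytes are CD56-low so no don't-care coin flip can
make them satisfy the NK row).

What the generator does *not* emulate: instrument artifacts (spillover,
bead drift, doublets), heavy-tailed or skewed mode shapes, dim/intermediate
marker levels, correlated marker noise within a cell, and batch effects.
Passing the benchmark therefore demonstrates the machinery is correct under
the model's own assumptions — it does not certify performance on real
CyTOF data, where mode overlap and intermediate expression are the
dominant difficulties.

## Problem sizes and runtimes

The standard benchmark is 3 replicates × 20,000 events × 12 markers
(pooled fits and landmarks on 60,000 events), chosen to exercise the sparse
solver and graph code at realistic single-sample scale while a full
pipeline run stays around 3–4 minutes on one core.  The replicate-variation
study uses 5 × 10,000 events: frequency correlations are composition-level
quantities and insensitive to per-replicate depth.  Measured on these
fixtures: overall accuracy ≈ 99.6%, novel population recovered as unknown
≈ 99%, accuracy spread over walk-graph k ∈ {10, 20, 30} ≈ 0.1 percentage
points, mean non-rare per-type frequency correlation ≈ 1.0 — with the rare
0.5% population the consistent weak spot (recall ~0.6–0.7), as expected
when a population's subset barely clears the community-size floor.

## Known limitations

* Binary marker states only; dim/intermediate populations are outside the
  model.
* Rare populations (≲ 0.5%, i.e. near `min_cluster_size` after score
  partition) get unstable landmarks and depressed recall; the Canberra
  distance is the metric that exposes this.
* Marker states rarer than ~1% of all events break the per-marker mixture
  fit itself (see above).
* The score partition threshold (½) and the two graph k's are inherited
  conventions; the robustness test varies the walk-graph k only.
* Landmarks join the walk graph as ordinary points; other couplings (e.g.
  landmark-only boundary edges) are conceivable but unimplemented.
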