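# Methods

`shollkit` computes *Sholl descriptors* of dendritic morphology: for a
neuron `N`, modeled as a collection of rooted binary trees in 3-space
sharing a common root (the soma, placed at the origin), each descriptor
is a compactly supported function of normalized distance from the soma
with values in the reals or in the space of persistence diagrams.
Functional distances between descriptor functions induce pseudo-metrics
on neuron sets — pseudo because isometric neurons are at distance zero —
which drive clustering, class detection, and metric-learning
classification.

## Neuron model

An SWC reconstruction is parsed into samples (id, type, x, y, z, radius,
parent). By default only soma (type 1) and dendrites (types 3, 4) are
kept; axons are excluded from the dendritic morphometry. All type-1
samples collapse to a single root at the first soma sample's
coordinates, and the reconstruction is translated so the root sits at
the origin. Multifurcations are binarized by inserting duplicate-position
nodes joined by zero-length edges, so every non-soma branchpoint has
exactly two children; this preserves all lengths and radial distances.
Node kinds follow child counts: termination (0), continuation (1),
bifurcation (2). Per primary tree the binary identities hold exactly:
branches = 2·degree − 1 and bifurcations = degree − 1, where degree is
the leaf count.

Key lengths: the span `R(N)` is the radius of the smallest soma-centered
ball containing the neuron (attained at a node, because distance to the
origin is convex along a straight segment), and `L(N)` is the longest
soma-to-tip path length. Radial-domain descriptors are normalized by
`R(N)`, path-domain ones by `L(N)`, making every descriptor
scale-comparable across neurons; units (micrometres in SWC) never enter
a normalized function's domain.

**Ball restriction.** The soma component of `N ∩ B(0, r)` keeps each
segment up to its first exit from the closed ball (the inside part
reachable from the soma is a single initial interval of the segment, by
convexity); exit points become terminations and distal subtrees are
dropped. Ties (a node exactly on the sphere) resolve to inclusion.
A segment leaving a node that lies exactly on the sphere is dropped by
the geometric restriction but kept as a zero-length grazing tip when the
restriction is taken as a limit from the right — the convention the
r-varying TMD needs (below).

## The eight descriptors

All step functions are right-continuous; evaluation at t = 1 uses the
last value.

- **Branching pattern** — leaves minus bifurcations within radius r.
  With this sign the value at t = 1 is the number of primary branches
  (each stem tree contributes leaves − bifurcations = 1); a
  `literal_sign` option provides the opposite convention
  (bifurcations − leaves). Available on the radial or the path domain.
- **Tortuosity** — mean over branches entirely inside the ball (and
  connected to the soma inside it) of branch path length / endpoint
  chord length. Equal to 1 until the first branch is complete;
  zero-length branches (binarization artifacts) and coincident-endpoint
  branches are excluded. Dendritic tortuosity in real reconstructions
  lies in [1, 2].
- **Flux** — at radius r, the sum over all sphere crossings of the
  unsigned angle (radians) between the parent-to-child segment direction
  and the outward radial normal. Crossings are quadratic roots per
  segment (at most two, by convexity); angles are computed as
  `atan2(|d × n|, d·n)`, which is exact and well-conditioned where
  `acos(d·n)` loses half its digits (a stem leaving the soma radially
  crosses every small sphere parallel to the normal). Near-zero
  quadratic discriminants are clamped so a sphere grazing a node — e.g.
  the farthest tip at r = R(N) — registers identically in every rotated
  frame. Flux is not piecewise constant, so the function is a grid
  discretization (100 equispaced t values by default).
- **Taper rate** — path-domain: the dendritic diameter (2·radius) of
  the branching node with the largest path distance ≤ t·L(N); the soma
  diameter before the first branchpoint. All-zero radii (common in
  archives that do not record thickness) produce a warning and the zero
  function.
- **Leaf index** — the number of terminations reachable along
  soma-fleeing paths from the branchpoint with the largest radial
  distance ≤ r (the soma if none, giving the total degree at t = 0).
  Branchpoint ties at one radial distance resolve to the larger count.
- **Energy** — nodes act as unit charges: the value at r is the
  Euclidean norm of `Σ v/|v|³` over bifurcation and termination nodes
  with |v| ≤ r (inverse-square law; the exponent is configurable). The
  norm is isometry invariant; under uniform scaling by s the values
  scale by s⁻². Charges are bifurcations and terminations only —
  continuation samples are geometry carriers, not nodes of the tree
  model — which also keeps the descriptor independent of resampling
  density. The **energy polarity** construction clusters the per-node
  contribution vectors by their pairwise angles (average linkage, cut at
  2) and scores the angle between the two clusters' summed fields:
  near π for bipolar neurons, small for unipolar ones.
- **Total wiring** — the total dendritic length of the ball
  restriction, a continuous nondecreasing function of r sampled on the
  union of a 100-point grid and the exact node radii (so the value at
  t = 1 is exactly the total dendritic length). Node breakpoints are
  evaluated at the raw node radius rather than `(radial/R)·R`, whose
  float round-trip can land below the node's own radius and flip the
  closed-ball tie.
- **Sholl-TMD** — the topological morphology descriptor (TMD) of the
  restriction, varying with r. The classical TMD assigns each leaf its
  radial distance; at every merge the larger-valued child survives and
  the other emits the bar (value, merge radius); the final survivor
  emits (value, 0). One bar per leaf; ties resolve to the smaller leaf
  id; the leaf-to-merge path decomposition is returned alongside the
  bars. The r-varying version is piecewise constant between consecutive
  node radii, with each interval's diagram computed at the left
  endpoint as a limit from the right (clip-point leaves carry start
  value exactly r, including zero-length grazing tips, which contribute
  zero-persistence bars). At t = 1 it equals the classical TMD.

## Pseudo-metrics

- Real-valued descriptors: exact Lp distance on the merged breakpoint
  partition (default p = 1), or the sup norm for p = ∞.
- Persistence diagrams: p-Wasserstein (default p = 2) with optimal
  partial matching against the diagonal, ground metric L∞ on the
  (start, end) plane (diagonal cost (start − end)/2; L2 ground
  available). Solved exactly by the assignment algorithm on the standard
  diagonally-augmented cost matrix, for any diagram size.
- Diagram-valued functions: the sum of Wasserstein distances over the
  union of the two breakpoint sets (right-continuous evaluation).
  Breakpoints closer than 1e−9 are merged, evaluating at the group
  maximum: without this, rounding-level breakpoint jitter (e.g. from a
  rotated coordinate frame) creates spurious full-size summands in which
  one function has switched diagrams and the other has not, and the
  construction would not even be invariant under isometries. A
  `weighted` variant multiplies each term by its interval length,
  turning the sum into an integral over [0, 1].

Distance matrices compute each neuron's descriptor once; neurons whose
descriptor computation fails are excluded and reported, never silently
dropped.

## Analyses

- **Detection** — for a labeled set under one pseudo-metric, the
  detection rate of class `l` is the maximum over all closed balls
  (every dataset point as center, every distinct distance as radius) of
  `100·min(recall, precision)`, where recall is the fraction of class
  `l` inside the ball and precision the ball's purity. The witness ball
  is returned and can be re-scored independently. The search is
  exhaustive by construction, O(n² log n).
- **Combination** — distance matrices are normalized by their mean
  off-diagonal entry, and convex weights on an equispaced simplex grid
  (step 0.1 by default) maximize the ratio of mean inter-class to mean
  intra-class combined distance. Both means are linear in the weights,
  so the grid scan is O(1) per point after precomputing per-matrix
  means; ties resolve to the lexicographically smallest weight vector.
  Mean normalization makes the objective invariant to rescaling any
  input matrix.
- **Vectorization** — each of the six real-valued descriptors (energy,
  flux, leaf index, branching, wiring, tortuosity) is summarized by its
  exact integral over [0, 1], maximum, argmax, and value at 1, giving a
  24-dimensional morphology vector. Features are z-scored across the
  dataset before Euclidean use; zero-variance features map to 0.
- **Hierarchical clustering** — scipy's agglomerative linkage (single /
  complete / average / Ward) on the precomputed condensed matrix or on
  a feature table under the Euclidean metric. Ward on a non-Euclidean
  pseudo-metric is the usual Lance–Williams extension; heights are
  nondecreasing for the supported linkages. scipy's merge ordering is
  deterministic, though its internal tie-breaking is its own.
- **LMNN metric learning** — a linear transform L (distances
  `‖L(x−y)‖`, a Mahalanobis pseudo-metric) minimizes the large-margin
  nearest-neighbor loss: pull each point's k = 3 same-class target
  neighbors, push differently-labeled impostors beyond a unit margin
  (push weight 0.5). Optimization is plain gradient descent from the
  identity with an adaptive step (grow 1.1× on improvement, halve on
  overshoot), deterministic by construction. If the optimized transform
  does not improve training-set KNN accuracy over the Euclidean
  baseline, the identity is kept — the learned space never degrades
  training KNN performance. Exposed as a scikit-learn-style
  transformer (`fit`/`transform`/`get_params`).
- **Classification protocol** — stratified 70/30 train/test split
  (seeded); LMNN fit on the training set; repeated stratified 10-fold
  cross-validation (3 repeats) of a KNN classifier (k = 5) in the
  learned space, reported as mean ± sd; a final KNN fit on the full
  training set scored on the held-out test set. Fold counts reduce with
  a warning when the smallest class is below the fold count. Because the
  transform is learned once on the whole training set before CV, fold
  scores are mildly optimistic; the held-out test accuracy is the
  unbiased number. The KNN k = 5, LMNN k = 3, and 3 repeats are package
  defaults (no canonical values exist for them).
- **Stability probes** — node positions (soma fixed) are jittered
  uniformly in a ball of radius ε and the descriptor pseudo-distance to
  the original is averaged over 5 draws. For branching, wiring, leaf
  index, energy and flux the curve tends to 0 with ε. Tortuosity is
  exempt: an arbitrarily small jitter can turn a short straight branch
  into one with a bounded-away-from-1 path/chord ratio, a known
  instability of the ratio construction.

## Synthetic neurons

The generator emulates labeled populations of dendritic arbors for
recovery experiments, not any specific archive's statistics. Per
archetype: `n_stems` stem directions (isotropic, or inside a polarity
cone; `bipolar` alternates the cone with its opposite), a random full
binary tree topology with exactly `target_degree` leaves per stem
(realized exactly, so the counting identities are testable as integers),
and an embedding in which each branch is a chain of 8 steps of
~7 ± 1.5 μm. Spans land in the 150–350 μm range typical of dendritic
arbors, keeping energy and taper numerically well-conditioned
(normalization makes the absolute scale irrelevant to the descriptors).

Two choices matter for what the recovery experiments mean:

- **Tortuosity is a per-branch meander around a fixed axis** (ballistic
  tropism, as in standard dendritic growth models), not a cumulative
  random walk: each step deviates independently from the branch axis by
  |N(0, σ)| radians, and daughters inherit the axis, not the wandered
  direction. Independent deviations shrink every chord by the same
  expected factor, so the normalized positions of branchpoints are
  statistically unchanged while the path/chord ratio responds directly
  to σ — classes "differing only in tortuosity" really do differ only
  in tortuosity. The dial is calibrated to the biological range: σ =
  0.15 gives mean branch tortuosity ≈ 1.01 (straight, granule-like), σ
  = 0.8 gives ≈ 1.35 (tortuous, Martinotti-like); values stay well
  below the empirical ceiling of 2.
- **Depth profiles co-vary topology and branch length**: near-soma
  bursts split shallow branches and keep internal branches short
  relative to terminal ones; distal tufts grow a long trunk before a
  short branching crown. Topology alone does not move the normalized
  radial position of branchpoints; the length modulation is what makes
  the profiles morphologically distinct (and what the branching/wiring
  descriptors see).

What the generator does *not* emulate: reconstruction noise and
truncation artifacts, soma geometry beyond a point, diameter
measurement error, axonal arbors, and within-class covariance structure
of real populations. Recovery results on synthetic classes therefore
show that the descriptors detect the morphological contrasts they
target when those contrasts are present — not that any particular real
cell classes are separable.

Populations derive per-neuron seeds from a master seed
(`numpy.random.SeedSequence`), so outputs are byte-identical across
runs; degenerate geometry retries on a fresh substream, capped at 100.

## Numerical conventions

- Closed-ball ties resolve to inclusion everywhere; restriction radii
  at node breakpoints are taken as the raw node radius to avoid float
  round-trip tie flips.
- Step functions are right-continuous with first breakpoint 0.
- Sphere-crossing quadratics clamp discriminants within rounding error
  of zero to tangency; tangent (double) roots count once.
- Wasserstein cost matrices use a finite "forbidden" cost larger than
  any feasible matching instead of infinities.
- Degenerate inputs: a soma-only neuron yields constant descriptor
  functions (0, or 1 for tortuosity, soma diameter for taper) and empty
  diagrams; zero-variance features z-score to 0; single-class
  classification reports accuracy 1.0 with a warning.

## Study sizes used by the bundled experiments

The test suite and `scripts/acceptance.py` run: toy closed forms
(4–8 node trees); isometry invariance on 20 small synthetic neurons ×
20 random orthogonal maps; matching/quadrature oracle checks on 100
random diagram pairs and 10⁴-sample Riemann sums; structural identities
on 100 random trees; pseudo-metric axioms on 200 sampled triples per
descriptor over 14 neurons; recovery at 20 neurons per class and the
classification pipeline at 3 archetypes × 30 neurons. These sizes give
stable detection rates and accuracies while keeping a full run in the
low minutes on one CPU.

## Known limitations

- Real NeuroMorpho datasets are supported through the SWC reader, but
  no accession lists ship with the package; the bundled experiments are
  synthetic.
- The flux and wiring functions are grid discretizations between their
  exact anchor points; Lp distances between them inherit the grid
  resolution (refinable via `n_grid`).
- The Sholl-TMD breakpoint-union distance follows the printed summation
  convention; it weights neurons with many nodes more heavily than an
  interval-weighted integral would (the `weighted` flag provides the
  latter).
- LMNN uses a dense O(n²·k) impostor sum per iteration — fine for
  hundreds of neurons, not tuned for tens of thousands.
- Axonal morphology is out of scope; structure type 2 is filtered by
  default.
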