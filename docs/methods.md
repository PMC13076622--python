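# Methods

crownclust groups delineated tree point clouds by species without any
training data: each tree is reduced to a compact rotation-invariant
shape descriptor, the descriptors are fused into a weighted graph by
rank products, and modularity-based community detection recovers the
species groups. This note records the model, its assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Shape descriptors

A tree is a set L_t of 3D points (metres, z up). Its descriptor
F(t) has 23 components in six groups:

* **f1 (3 components, metres).** PCA is applied to the centred
  coordinates; d1 >= d2 >= d3 are the standard deviations of the
  projections onto the principal directions, and
  f1 = [d1-d2, d1-d3, d2-d3]. Sorting descending makes every component
  non-negative and the vector exactly invariant to rigid motion.
  Population (1/n) standard deviations are used.
* **f2 (scalar, (0,1]).** A voxel grid V with isotropic edge delta
  counts points per voxel. A symmetrised grid S revolves the cloud
  around the vertical axis through the centre of mass c: point l is
  counted in voxel s whenever | |l_xy - c_xy| - |s_xy - c_xy| | < delta
  and l lies in s's z-layer. f2 is the Jaccard index of the binarised
  grids; since every point's own voxel satisfies the radial condition,
  V(b) is contained in S(b) and f2 = |V(b)|/|S(b)|. An axisymmetric
  crown gives f2 near 1; strong crown asymmetry drives it down.
* **f3', f4', f5' (per-slice profiles).** Per z-layer: the Jaccard
  symmetry of the layer's V and S slices; the total S count of the
  layer; and the maximum point distance from the vertical axis (from
  raw point radii, not voxel centres). Layers with no points are
  dropped from all three profiles; surviving layers keep their physical
  position (layer midpoint normalised by the grid height), so gaps do
  not distort the abscissae.
* **f3, f4, f5 (6 coefficients each).** Each profile is compressed by
  an unpenalised least-squares fit of six cubic B-splines on a uniform
  open knot vector over [0,1]. A fixed basis keeps trees of different
  heights comparable; zero penalty makes the fit reproducible without a
  smoothing hyperparameter. Profiles shorter than six slices get the
  minimum-norm solution.
* **f6 (scalar, >= 0).** The L1 residual of the f3' fit — a measure of
  how irregular the slice-wise symmetry profile is.

Grid anchoring: the origin sits at the bounding-box minimum, with x and
y snapped so that c_xy lies exactly at a voxel centre. This makes the
radial symmetrisation condition symmetric around the axis and the
degenerate axis-only tree exact (f2 = 1). Points are binned half-open,
[i*delta, (i+1)*delta); the S z-condition uses the same half-open rule,
because the literal symmetric band |l_z - s_z| < 0.5*delta would leave
the lowest point of every tree (which sits exactly on the grid edge) in
no layer and break the V(b) ⊆ S(b) inclusion.

Scale behaviour worth knowing: duplicating every point leaves f2, f3,
f5 and f6 unchanged and scales f4 linearly; since vector features are
compared by cosine distance downstream, the pipeline is insensitive to
uniform density changes — the mechanism behind its decimation
robustness.

**Parameters.** `delta` defaults to 0.5 m (grids at 0.125–2 m are
supported for resolution experiments; 2 m voxels visibly degrade
separation, very small voxels make the grids sparse and fragile).
A viable tree needs at least 10 points and 2 occupied z-layers.

## Graph construction and community detection

For every unordered tree pair and every feature, a distance is computed
(absolute difference for scalars, 1 - cosine similarity for vectors;
self-pairs are excluded since their zero distances would distort the
rank distribution). Distances are converted per feature to standard
competition ranks ("1224": ties share the smallest applicable rank),
and fused into one edge weight

    w_uv = prod_f (1 - R_f(u,v) / maxR_f)^alpha .

Ranking makes the fusion exactly invariant to any strictly increasing
transform of a single feature's distances, so features on incompatible
scales combine without normalisation. `alpha` (default 2) sharpens the
contrast between strong and weak edges; at alpha = 0 every weight is
exactly 1 (the max-rank factor is 0^0 = 1) and only topology carries
information.

The `beta` share (default 0.1) of weakest edges is discarded before
community detection. Edges are ordered by the alpha-independent base
product (alpha = 1), with lexicographic tree-id pairs breaking ties
deterministically. Ordering by the base product rather than by w itself
is deliberate: for alpha > 0 the two orderings are identical, while at
alpha = 0 all weights tie at 1 and ordering by weight would prune an
arbitrary lexicographic subset; with the base ordering, heavy pruning
(beta around 0.95) recovers good separation even on the unweighted
graph. Zero-weight edges are dropped in any case — they carry no
modularity signal.

Communities come from weighted fast greedy modularity optimisation
(Clauset–Newman–Moore): starting from singletons, repeatedly merge the
community pair with the largest modularity gain while any gain is
positive. The implementation is native, with a lazy max-heap keyed by
(-dQ, community i, community j): equal gains resolve to the smallest
index pair, so repeated runs are byte-identical. Tests cross-check the
result against python-igraph's fast greedy (identical Q to 1e-9 on
random graphs) and against exhaustive search over all partitions of
small graphs. An optional Leiden back-end (leidenalg) is available for
comparison runs; it is stochastic and outside the default path.

Modularity is the standard weighted Q = sum_c (e_c - a_c^2), with e_c
the fraction of edge weight inside community c and a_c its fraction of
weighted degree. Edgeless graphs return all-singleton communities with
Q reported as 0 and a warning.

## Classification and outliers

A community is labelled by plurality vote over at most k of its trees
with known species (uniform sampling without replacement, one child
seed per community; ties go to the lexicographically smallest species).
Sampled trees keep their own ground-truth label. With perfect
communities, k = 1 classifies every tree correctly.

Outlier scoring uses two complementary signals. (1) The candidate's
mean edge weight over the *unpruned* complete weight matrix, and the
ascending competition rank of that mean among all trees — rank 1 marks
the tree least similar to everything else. Means are accumulated with
exact summation so trees with identical features tie exactly. (2) The
size of the candidate's community (excluding itself) after aggressive
pruning at beta = 0.7; 0 means the candidate is isolated.

## Evaluation metrics

Rand Index and Adjusted Rand Index are computed from the contingency
table via the pair-counting and permutation-model formulas; when the
ARI denominator vanishes (both partitions trivial) the score is 1 by
convention. Classification quality reports a true-by-predicted
confusion matrix, overall accuracy, and macro-averaged one-vs-rest
precision, recall, specificity and F1; a class never predicted
contributes precision 0 (with a warning) so macro averages stay
comparable across runs.

## Synthetic forest generator

The generator exists so that every stage is testable without
downloading survey data. A species is a profile: six control radii
interpolated piecewise-linearly over normalised crown height, a total
height range, a trunk fraction, a volumetric point density, an
azimuthal asymmetry amplitude (radius modulated by
1 + a*cos(azimuth - phi0) with a random phase), and Gaussian jitter.
A tree is drawn by uniform volumetric rejection sampling of the
asymmetric solid of revolution (crown point count is Poisson with mean
density x analytic crown volume) plus a trunk segment at 20 points per
metre on the axis. Crown interiors are filled, not just surfaces,
because terrestrial LiDAR returns occur throughout crowns and the
voxel-count feature needs interior mass. Per-tree height is drawn
uniformly from the species range and the radii scale linearly with it.
A single master seed drives per-tree child seeds through a counter, so
any tree is reproducible in isolation.

Two packs ship with the package:

* **default10** — ten species with clearly distinct profile *shapes*
  (cone, column, ellipsoid, umbrella, low-peaked, concave-taper, dome,
  squat ball, hourglass, asymmetric barrel), heights 4–30 m, low noise
  (0.05 m), and asymmetry used as the discriminating trait where shapes
  alone are close. Densities are derived per species from an analytic
  volume target of about 5,000 crown points for a tree at the mean
  height. This is the well-separated regime: the full pipeline recovers
  all ten species exactly (ARI = 1.0), also under 10% decimation and
  random vertical-axis rotations.
* **hard7** — seven deliberately overlapping broadleaf/conifer profiles
  with higher noise (0.15 m) and the imbalanced per-species counts
  164/183/22/39/158/25/100. This is the merging regime: communities
  blend similar species and ARI lands well below 1, which is what the
  semi-automatic workflow and the outlier tooling are for. Tests run
  this pack at one-eighth of the full counts to keep the suite fast.

What the generator does *not* emulate: branching architecture, foliage
clumping, occlusion and scan-shadowing, ground/understorey returns,
sensor noise models, or registration error. Passing tests therefore
demonstrate the correctness and internal robustness of the pipeline,
not field performance on terrestrial LiDAR; on real data the expected
regime is the hard7-like one (meaningful but imperfect communities).

## Numerical choices and edge cases

* Half-open voxel binning everywhere; boundary points go to the upper
  voxel.
* Jaccard of two empty sets is 1 (identical).
* Spline fits use `numpy.linalg.lstsq` (minimum-norm for short
  profiles); the f3' residual is the only residual kept (f6).
* Competition ranking via `scipy.stats.rankdata(method="min")`.
* Pruning removes floor(beta * |E|) edges; determinism is guaranteed by
  the (order key, pair) sort.
* Mean-weight outlier statistics use `math.fsum` so identical trees tie
  exactly in the rank.
* Degenerate inputs raise named errors: empty clouds, non-finite
  coordinates, trees with fewer than 10 points or fewer than 2 occupied
  layers, zero-norm feature vectors, communities with no labelled tree.

## Problem sizes

The standard protocol used throughout tests and the acceptance script
is 10 species x 10 trees at roughly 5,000 points per tree; robustness
checks repeat it 10 times under decimation to 10% and under random
rotations. The hard7 pack is exercised at scaled-down counts (about 85
trees). These sizes were chosen as the smallest at which the
statistical behaviour of interest (perfect recovery, merging, outlier
isolation) is stable across seeds.

## Known limitations

* The voxel features are robust, not exactly invariant, under rotation
  (axis-aligned voxelisation); the guaranteed bound in tests is 5%
  relative on well-resolved trees, and f1 alone is exactly invariant.
* At extreme sparsity (around 50 points per tree, i.e. 1% of the
  default density) a 0.5 m grid cannot resolve crown shape and
  separation degrades; decimation robustness holds down to about 10%.
* Greedy modularity maximisation is a heuristic with a resolution
  limit; very small species groups may be absorbed by larger ones, as
  the hard7 regime shows.
* The external-schema feature-JSON importer is best-effort: it maps
  common layouts (flat 23-vectors, case-insensitive field names) onto
  the package's schema and cannot anticipate arbitrary third-party
  formats.
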