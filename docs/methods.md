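# Methods

## The model

The admissible space for fiber centroids is a polygon with holes: the
outer endoneurium contour of a root or fascicle minus its vascular
profiles.  Coordinates are micrometres in an arbitrary section-local
frame; the statistics below are invariant under rigid translation and
uniform scaling, so no calibration beyond the µm scale is needed.  The
boundary convention (points on the outer ring are inside, points on a
hole ring are outside) makes the admissible set closed-minus-open; since
all sampling is continuous, the convention only affects input validation.

### The uniform null and SD_UG

The null hypothesis is complete spatial randomness (CSR) conditioned on
the observed fiber count and region: n points uniform over the admissible
area.  Points are ideal (zero radius); no hard-core exclusion reflecting
fiber caliber is imposed, so arbitrarily close simulated pairs are
allowed.  Uniformity is achieved by rejection sampling from the bounding
box, which is exact, simple, and cheap at the hole fractions seen in
sections (the sampler refuses regions whose admissible/bbox area ratio is
below 1e-6).  Draws are mapped as `lo + u·(hi − lo)`, which is what makes
the simulated statistic exactly equivariant under coordinate scaling for
a fixed random stream.

Each of S placements yields the mean kth-nearest-neighbor distance
`d_s = (1/n) Σ_i d_ik`; the null summary is `D_U = mean(d_s)` and
`σ_U = sd(d_s)` (sample SD, S−1 denominator — with S = 1000 the
distinction from the population SD is negligible, but it is pinned down
for exactness).  The observed statistic `D_G` on the real centroids then
gives the clustering index `SD_UG = (D_G − D_U)/σ_U`.  Because the null
is conditioned on the same region and n, shape, size, and count effects
cancel; because σ_U is the spread of *per-simulation means*, SD_UG of a
CSR pattern scored against its own null is approximately a standard
normal draw — the property the calibration test checks (mean ≈ 0, SD ≈ 1,
essentially no mass below −4).

No edge correction is applied to any distance, on either side of the
comparison: null and data share the identical geometry, so boundary bias
cancels in the difference.  The same reasoning applies to the K/L
estimator below.

Multi-fascicle roots: SD_UG is computed per fascicle and combined by
fiber-count weighting, `Σ_k n_k SD_UG^k / Σ_k n_k`, which always lies
between the fascicle extremes.  Per-class indices (PPN / γ / α) re-run
the null at the class count n over the full fascicle region — the class
null asks "if this many fibers of this type were placed at random in the
fascicle", which is the literal reading of computing the index
"separately" per subpopulation.

### Choice of k and the L-function diagnostic

k = 50 is the default neighbor order.  The normalized L-function
(`L(r) − r` with `L = sqrt(K/π)` and an uncorrected K estimator) is the
diagnostic for that choice: under CSR it is flat at 0, and its
Monte-Carlo envelope — pointwise min/max over uniform placements in the
same region — shows at which radii the observed pattern is denser than
chance.  The curve is annotated with the null-mean kNN radii for
k ∈ {25, 50, 75} so the neighbor order can be placed on the radius axis.
The normalization `L(r) − r` (a difference, not a ratio) is a package
choice; the raw K is exposed for users who need another convention.  The
envelope substitutes for analytic CSR bands deliberately: the same-region
simulation absorbs the edge bias that the uncorrected estimator carries.

### Cluster delineation

OPTICS (Ankerst et al. 1999) orders the centroids by density
reachability: the core distance of p is the distance to its
(min_pts − 1)th other point, the reachability of q from p is
max(core(p), d(p, q)), and points are visited by a priority queue of
smallest reachability with ties broken by ascending input index (this tie
rule makes runs deterministic and is part of the tested contract; a
brute-force reference and sklearn's OPTICS both reproduce the profile
exactly on tie-free data).  min_pts equals the user's minimum cluster
size (default 4).

Flat clusters come from an eps-cut of the ordering (DBSCAN-equivalent): a
point with reachability ≤ eps joins the current cluster; a point with
reachability > eps opens a new cluster if its own core distance is ≤ eps
and is noise otherwise; runs shorter than min_size are relabeled noise.
The cut is calibrated in SD units of the uniform null,
`eps = D_U + t·σ_U`, with t ≤ 0; t = 0 cuts at the null mean and the cut
tightens as t decreases.  Thresholds with eps ≤ 0 raise an explicit
infeasible-threshold error reporting the minimum feasible t = −D_U/σ_U,
rather than silently returning zero clusters.

Two calibrations are offered because the cut and the profile live on
different distance scales:

* **`knn-mean`** (default): the null is simulated at the index's neighbor
  order (k = 50).  eps then sits on the mean-50NN scale, far above any
  min_pts = 4 reachability of a dense pattern, so t = 0 yields a single
  cluster containing every fiber and the cut becomes informative only as
  t decreases toward the feasibility limit.  This is the literal reading
  of "threshold of −t SD" and reproduces the all-inclusive-cluster
  behavior at t = 0.
* **`scale-matched`**: the null is simulated at k = min_pts − 1, the same
  order as the core distances, so eps compares like with like.  This is
  the mode for recovering compact planted clusters against a diffuse
  background.

A caveat the package states rather than hides: because σ_U is the SD of
per-simulation *means*, σ_U/D_U is small (1–3% for typical n and k), so
moderate SD thresholds move eps only slightly below D_U in either
calibration.  At t = −4 the scale-matched cut sits at ≈ 0.9·D_U, which
on a parent–offspring pattern with a diffuse background still admits
occasional spurious background clusters and absorbs background points
lying inside clump footprints; measured planted-cluster recovery at that
cut is mean ARI ≈ 0.67 (the acceptance script reports the value), and
recovery peaks (mean ARI ≈ 0.94) at cuts near 0.4·D_U, i.e. much more
negative thresholds.  Users delineating sparse subpopulations should
either deepen the threshold or inspect the reachability profile
directly — both are exposed.

## Synthetic data

No segmented histology ships with the package, so generators stand in:

* `synthetic_region`: a star-shaped perturbation of a circle (default
  nominal diameter 400 µm, ±12% radial irregularity, 24 vertices) with
  two circular vascular holes of radius 5% of the diameter — sized like a
  primate lumbosacral ventral root cross-section.
* `generate_csr`: the null pattern itself.
* `generate_clustered`: a parent–offspring (Thomas-style) process —
  uniform latent parents, Poisson(children_mean) offspring per parent
  displaced by an isotropic Gaussian and re-sampled (not discarded) until
  inside the region, over a uniform background.  Chosen because it has an
  interpretable strength knob (offspring dispersion) and a CSR limit
  (dispersion at region scale, or no parents).
* `generate_mock_root`: a full root with three diameter classes drawn
  multinomially (defaults echo a sacral-level composition: 38% PPN, ~20%
  γ, rest α; totals conserved exactly).  The PPN subpopulation is clumped
  (dispersion 1.5% of the region diameter, ~15 offspring per parent) to a
  requested strength in [0, 1]; motor classes are uniform, mirroring the
  empirical pattern that small autonomic fibers cluster most.  Diameters:
  PPN lognormal (median 2 µm) truncated to (0, 4]; γ beta-shaped over
  (4, 10]; α right-skewed beta over (10, 20], the upper end matching the
  largest myelinated fibers in such roots.

What the generators do not emulate: fiber footprints (no minimum
inter-centroid distance), myelin, fascicle fragmentation during
embedding, segmentation noise, and anisotropy from oblique sectioning.
Passing tests therefore show the statistics and the extractor behave
correctly on point patterns with known structure — not that real roots
satisfy the generators' assumptions.

## Numerical and design choices

* Randomness: every entry point takes one seed; per-simulation and
  per-stage generators are spawned from a `numpy.random.SeedSequence`, so
  results are bit-reproducible and stages can be re-run in isolation.
* kNN distances use a k-d tree; ties are broken by distance value only,
  so coincident points are handled consistently.  OPTICS uses the full
  O(n²) distance matrix — ample for section-scale counts (≤ a few
  thousand fibers).
* Diameter bands are inclusive on the smaller class (4.0 µm → PPN,
  10.0 µm → γ), matching the ">4–10" / ">10" interval convention; both
  edges are user-overridable.
* When only area and perimeter are available, the effective diameter is
  the minor axis of the ellipse solving `area = πab` and Ramanujan's
  perimeter approximation (closed form; falls back to the
  equivalent-circle diameter within 1e-6 relative tolerance of the
  circular minimum, and rejects perimeters below it as inconsistent
  segmentation).  This is a stand-in for upstream dispersion-angle
  corrected diameters, which are used verbatim when supplied.
* Mann–Whitney comparisons are two-sided: exact enumeration when both
  groups have n ≤ 8 and the pooled data are tie-free, tie-corrected
  normal approximation otherwise.
* Fibers whose centroid falls in a vascular hole (segmentation noise) are
  handled by a caller-selectable policy (error / drop / warn), since no
  single convention is obviously right.
* Grid intensity uses half-open cells over the region bounding box with
  the last row/column closed, so counts always sum to n.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: null calibration uses 100–200 CSR replicates at n = 500,
k = 50, S = 200; planted-cluster recovery uses 25–50 seeds at n ≈ 200
with S = 200 nulls; the mock cohort is 30 roots (6 animals × 5 levels,
400–1000 fibers each) at S = 200.  Defaults in the library itself remain
k = 50, S = 1000.

## Known limitations

* SD_UG conditions on n; it measures arrangement, not abundance.
* Uncorrected K/L and kNN statistics are biased near boundaries; the
  design cancels the bias against the same-region null rather than
  correcting it, so curves should not be compared across regions of very
  different shape without care.
* The −4 SD default cut is permissive on the knn-mean scale (see the
  caveat above); cluster counts at moderate thresholds are best read
  comparatively (across roots, against sweeps) rather than as absolute
  cluster inventories.
* 2D only: clustering along the nerve axis is invisible to a single
  section.
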