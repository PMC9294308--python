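# Methods

## The evaluation problem

A cortical parcellation is a partition of the surface vertices into discrete
regions. A good *functional* parcellation should place its boundaries where
functional profiles change: vertex pairs inside one parcel should be more
similar than pairs straddling a boundary. Similarity between two vertices is
the Pearson correlation *R* of their functional profiles (the vector of
activity estimates across task conditions, or time points).

Classical criteria operationalize this directly:

* **Global Homogeneity** — mean within-parcel pairwise correlation, averaged
  (unweighted) across all parcels with ≥ 2 valid vertices.
* **Silhouette coefficient** — per vertex *i* in parcel *k* with *m_k*
  members, using dissimilarity 1 − R:
  w_i = mean dissimilarity to the other m_k − 1 members;
  b_i = mean dissimilarity to all *N* vertices pooled over all parcels that
  share a mesh edge with *k*; S_i = (b_i − w_i) / max(w_i, b_i).

Both are inflated by the *spatial smoothness* of cortical maps: correlation
falls off with on-surface distance, and within-parcel pairs are on average
closer together than between-parcel pairs. Any parcellation — even one
unrelated to the data — therefore scores above chance level, and smaller
parcels score higher.

## The distance-controlled boundary coefficient (DCBC)

The DCBC removes this bias by comparing only vertex pairs of matched
on-surface distance. All qualifying pairs (both vertices unmasked, both
labels non-zero, distance within 0–35 mm by default) are assigned to
half-open distance bins (lo, hi] of equal width (1 mm default). Per bin *i*
the correlation difference is

    d_i = (mean within-parcel R) − (mean between-parcel R).

Assuming independent vertex pairs, var(d_i) ≈ 1/n_w,i + 1/n_b,i where n_w,i
and n_b,i are the within/between pair counts, so each bin's precision is
n_w,i·n_b,i/(n_w,i + n_b,i). The DCBC is the precision-weighted average of
d_i over the bins containing both pair kinds, with weights normalized to
sum 1; the un-weighted bin mean is reported alongside. Bins missing either
pair kind are excluded from both averages and reported. For a parcellation
unrelated to the data the expected DCBC is zero at every spatial scale.

Distances are graph shortest paths (Dijkstra) through the triangle edge
graph, with Euclidean edge lengths, truncated at 50 mm; pairs beyond the
cutoff are simply absent and never evaluated. Matrices from several
surfaces (subjects, hemispheres with matched vertex indexing) can be
combined by an available-case mean.

## Null model: rotated icosahedral parcellations

Parcel centers are the 10ν² + 2 vertices of a frequency-ν geodesic sphere
(ν = 2, 4, 6, 8, 10 → 42, 162, 362, 642, 1002 parcels). A random
parcellation rotates the centers by three independent angles uniform on
[0, 2π) about x, y, z (composed Rz·Ry·Rx — the stated sampling scheme,
which is not Haar-uniform on SO(3); kept as such deliberately) and assigns
each surface vertex to the nearest rotated center by great-circle ordering,
ties to the lowest center index. Empty parcels keep their label so parcel
identity is stable across rotations.

## Synthetic data

All simulation studies run on geodesic spheres of radius 100 mm (the
standard template-sphere radius). Two map generators are provided:

1. **Neighbor-averaging smoothing**: i.i.d. N(0, 1) values per vertex and
   condition, then n iterations of v ← ½·v + ½·(mean of edge neighbors)
   per condition. The iteration count is calibrated by doubling-plus-
   bisection so the realized spatial autocorrelation curve has a requested
   half-distance (distance at which the mean pair correlation first falls
   to half its first-populated-bin value; default target 15 mm).
2. **Distance-matched Gaussian process** (the default for validation):
   profiles drawn with covariance C_ij = f(d_ij), where f is a compactly
   supported exponential decay, f(d) = (e^(−d/λ) − c)/(1 − c) with
   c = e^(−cutoff/λ), f ≡ 0 beyond the cutoff. λ is calibrated by bisection
   on the *analytic* bin-averaged curve (no sampling), and C is factored
   exactly by Cholesky, so the realized pair correlation equals f(d) in
   expectation — the sampled correlation structure is an exact function of
   the same distances the criterion bins on.

The second generator exists because of a metric subtlety that matters on a
single regular mesh. Diffusion-style smoothing yields correlations that
follow the *intrinsic* (arc) geometry of the sphere, whereas the criterion
bins pairs by graph shortest-path distance, which on a regular icosphere
overestimates arc length anisotropically — by up to ~22% for pairs running
diagonal to the mesh edges. At fixed graph distance, within-parcel pairs
then have systematically smaller arc distance and higher correlation,
producing a positive boundary coefficient at *every* bin width for
parcellations that are unrelated to the data. (Empirically: binning the
same smoothed maps by exact great-circle distance removes the effect.)
Multi-subject cortical data do not share this pathology — graph distances
averaged over many irregular individual surfaces are a clean monotone
function of true distance — so a faithful desk-scale emulation must tie the
generated correlation structure to the measured distances, which is exactly
what the Gaussian-process generator does. The exponential kernel family is
used because it is empirically positive definite under this graph metric
(smallest covariance eigenvalue ≈ 0.1 on the test spheres), whereas
Gaussian and Matérn kernels are not, and repairing them by eigenvalue
clipping distorts the correlation function enough to reintroduce the bias.
The cost of the exponential shape is a kink at zero distance: short-range
correlations are lower than those of heavily smoothed maps, so the
un-binned correlation difference in our simulations (~0.43) sits somewhat
below what maps smoothed with a large geodesic Gaussian kernel produce.

What the generators do **not** emulate: measurement noise, inter-subject
boundary variability, curvature-dependent smoothness, and the irregular
vertex spacing of real cortical meshes. Passing tests therefore demonstrate
correctness and bias behaviour of the *criteria* under controlled
smoothness, not performance on real fMRI data.

## Simulation scales and problem sizes

* Unit tests use frequency-2 to frequency-8 spheres (42–642 vertices) with
  exhaustive brute-force oracles (Floyd–Warshall shortest paths; literal
  pair-enumeration criteria).
* The zero-expectation study runs 20 maps × 5 scales on a frequency-16
  sphere (2562 vertices, ~6.6 mm vertex spacing).
* The scale-ordering, bin-width, and variance-reduction studies run on a
  frequency-32 sphere (10242 vertices, ~3.3 mm spacing, ~2.7 M vertex pairs
  within 50 mm): with 1002 parcels this keeps ~10 vertices per parcel,
  the closest desk-scale approximation of the 32k-vertex template regime
  (~32 per parcel); 20 maps for the ordering/bin-width studies and 50 maps
  for the variance-reduction study.

## Known limitations

* **Residual small-bin bias at coarse vertex spacing.** Within a distance
  bin, within-parcel pairs sit slightly closer than between-parcel pairs;
  the resulting positive bias shrinks with the bin width (non-significant
  at 0.2 mm bins in our simulations, as in the original analysis) but at
  1 mm bins on a 6.6 mm-spacing surrogate a residual of ≈ +0.001 remains
  detectable with ~100 simulations. On 2 mm-spacing cortical meshes the
  same effect is several-fold smaller. Consequence: with 20 simulations per
  scale the 1 mm-bin weighted DCBC is *approximately* zero-centred, but a
  strict ±2 SE check across five scales is marginal and can fail.
* Graph shortest paths are not exact polyhedral geodesics; the anisotropic
  overestimation discussed above is inherent to single regular meshes.
* Spectral parcellation uses a correlation affinity (negatives clipped,
  zero diagonal) and normalized-Laplacian spectral clustering with k-means;
  the affinity choice is a documented default, and spatial contiguity of
  the clusters at full resolution is not guaranteed.
* The rotation null samples angles uniformly per axis, not uniformly on the
  rotation group (kept to match the stated procedure).
* Numerical conventions: distances in mm as float64, 1e-6 mm comparison
  tolerance in tests; a distance exactly on a bin edge falls in the lower
  bin; dissimilarity 1 − R is not clipped and may exceed 1; degenerate
  group t statistics (zero SE) are reported as signed infinity rather than
  an error; Homogeneity averages parcels unweighted by size (size-weighted
  variant available as an option).
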