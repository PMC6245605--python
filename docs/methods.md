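# Methods

## Overview

shapeclust clusters a set of protein 3D models by local/global shape rather
than by sequence. The workflow is: read PDB models → structurally superpose
pairs → extract point-cloud shape descriptors from the aligned poses →
build per-descriptor distance matrices → normalize and fuse → cluster →
(optionally) score against ground-truth labels with the Rand index. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Structural superposition

`superpose.kabsch` computes the optimal rigid superposition (proper
rotation, det = +1; reflections excluded) minimizing coordinate RMSD.
`superpose.tm_align` is a deliberately simplified iterative aligner, not a
re-implementation of any published executable:

* Three seed alignments: the best gapless threading of one chain along the
  other (scored by TM-score), a global dynamic-programming alignment of
  Cα-geometry secondary-structure strings, and a DP alignment of the
  equally weighted combination of the secondary-structure agreement and the
  TM score matrix of the gapless superposition.
* Each seed is refined by alternating Kabsch superposition on the current
  residue pairs with a DP pass over Sᵢⱼ = 1/(1 + (dᵢⱼ/d₀)²) (linear gap
  penalty −0.6, ties broken diagonal > up > left), until the pair set is
  stable or 30 iterations. The best-scoring alignment ever evaluated is
  kept, so the result never scores below the best seed.
* TM-score: TM = (1/L_target) Σ 1/(1 + (dᵢ/d₀(L_target))²) with
  d₀(L) = 1.24·(L−15)^⅓ − 1.8, clamped below at 0.5 Å because the raw
  formula is negative for L ≤ 18. The score is asymmetric in the choice of
  target; both normalizations are reported and the TM-distance matrix uses
  1 − (TM_ab + TM_ba)/2 so the matrix is symmetric by construction.

Secondary structure is assigned from Cα pseudo-geometry alone (the
i→i+2/i+3/i+4 distance windows; helix ≈ 5.4/5.1/6.2 Å, strand extended
≥ 6.3/9.0 Å; thresholds configurable). This needs no side chains or
hydrogen-bond geometry, which the models may not have; it is deliberately
coarse and only drives alignment seeding.

## Descriptors

All four descriptors operate on a point cloud with unit surface normals
(smallest-eigenvalue direction of the k-neighborhood covariance, oriented
toward a viewpoint). Defaults (`DescriptorConfig`): neighbor_k = 10,
support radius 8 Å, 3DSC bins 12 × 11 × 15 with minimum radius 0.1 × support
and density radius δ = 2 Å, RSD plane-radius clamp 20 Å, 11 bins per angular
feature (hence the 33-dimensional FPFH). These suit dense heavy-atom
clouds.

For Cα-only clouds `DescriptorConfig.for_calpha()` is provided
(neighbor_k = 30, support 12 Å, 3DSC bins 6 × 5 × 5): with one point per
3.8 Å of chain, a 10-point neighborhood spans only the chain tube, where a
surface normal is ill-defined, and a 1980-bin shape-context histogram over
~15 in-support points is almost everywhere empty, so histograms of noisy
copies decorrelate. Wider neighborhoods reach spatially adjacent secondary
structure elements; coarser bins keep O(1) expected counts per bin.

Numerical choices that matter for reproducibility:

* Histogram binning snaps the scaled feature value to 10⁻⁹ of a bin width
  before flooring, and circular features (θ, azimuth) wrap modulo the bin
  count. Without this, features that sit exactly on a bin edge (common in
  idealized geometry: θ = ±π, coplanar normals) land in different bins for
  bit-jittered copies of the same shape, violating rigid-motion invariance.
* k-nearest-neighbor sets break distance ties by point index after snapping
  distances to 10⁻⁹ Å, for the same reason.
* The default viewpoint (normal orientation and the VFH direction) is the
  cloud centroid plus three bounding radii along the cloud's principal
  axis, sign fixed by the third moment along it. Because this is intrinsic
  to the cloud, it co-rotates under a common rigid motion of the inputs and
  descriptor-based distances are invariant to such motions (verified to
  1e-6 end-to-end). A world-fixed offset would not be.
* RSD inverts the chord relation exactly for normal angles α ≥ 0.1 rad and
  uses the first-order Taylor inversion r ≈ d/α below; radii are clamped at
  the plane radius (20 Å), and an isolated anchor reports
  (plane radius, plane radius) with a warning.
* Degenerate neighborhoods (zero covariance) get the +z normal with a
  warning; an anchor with an empty 3DSC support contributes a zero vector.

## Distances, correspondence, and fusion

The descriptor-space RMSD (root-mean-square Euclidean deviation between
corresponding per-point vectors) assumes equal L and a point correspondence
between two proteins, which is not defined for arbitrary structures. The
package's resolution: anchors are the Cα atoms of structurally aligned
residue pairs, with the full selected cloud as support. In the default
pairwise mode every unordered pair is aligned and descriptors are extracted
on that pair's aligned pose (O(n²) alignments and extractions). The
reference mode aligns every model to the first one, keeps the reference
residues aligned in all models as the common anchor set, and extracts once
per model — an O(n) approximation appropriate for large sets.

Raw descriptor scales differ by orders of magnitude (an FPFH distance is
tens of histogram units; an RSD distance is a few Å), so each matrix is
divided by its largest off-diagonal entry before fusion; the literal
unweighted sum of raw matrices remains available
(`fuse(..., require_normalized=False)`). Fusion weights are either all 1
(equal scheme) or, in the silhouette scheme, each descriptor's maximum
average silhouette width of k-medoids clusterings over the k range, clamped
at 0 (falling back to equal weights if all clamp).

## Clustering and model selection

k-medoids operates directly on the distance matrix: random medoid
initialization, alternation of nearest-medoid assignment and medoid update
(member with the smallest within-cluster distance sum), then PAM swap
improvement until no single medoid/non-medoid exchange lowers the total
cost; best of 10 restarts, default seed 42, all ties broken by lowest
object index. The swap phase is what makes the heuristic reliably match
exhaustive medoid search on small instances. Agglomerative clustering is
scipy's average linkage cut at k; DBSCAN is scikit-learn's with a
precomputed metric, eps defaulting to the 25th percentile of off-diagonal
distances and min_pts = 4, and noise points relabelled as singleton
clusters so silhouette and Rand stay defined.

Silhouette widths follow the standard definition with sᵢ = 0 for members of
singleton clusters; the cluster count is chosen by maximizing the average
width over k = 3…25 (capped at n−1), ties to the smallest k. The Rand index
is the plain (unadjusted) pair-counting index; the adjusted version is
reported alongside in pipeline reports, clearly labelled. When only part of
a dataset is annotated, the index is computed on the labelled subset.

## Synthetic benchmark

The generator emulates a cohort of immunoglobulin-variable-domain-scale
models with annotated structural subsets. A self-avoiding Cα trace
(~110 residues, exact 3.8 Å spacing, alternating ideal-helix and
zigzag-strand segments, dummy N/C/O atoms per residue) is hinge-perturbed
per family (8 random hinges, angle sd 0.05 rad per Å of requested
divergence; default 3 Å); members add per-atom Gaussian noise (default
0.3 Å — a separation/noise ratio of 10) and a random rigid motion. Default
family sizes are 38/42/22/12/12/11 (137 models). Everything is
deterministic given the seeds, and models are written as legal PDB files so
fixtures exercise the real I/O path.

What the benchmark does not emulate: real side-chain packing, Ramachandran
statistics, loop-length variation within a family, or homology-modelling
artifacts. Passing the recovery tests shows the pipeline separates rigid
shape families whose internal variation is small relative to between-family
divergence; it does not certify accuracy on real antibody models, where
within-family variation is structured rather than isotropic.

Problem sizes in the shipped experiments: the headline recovery experiment
runs the full 137-model cohort with Cα clouds, reference-mode alignment,
all four descriptors, silhouette-weighted fusion and silhouette model
selection over k = 3…25 (about a minute on one core); unit and property
tests use 2–3 families of 3–4 models at 40–60 residues.

## Known limitations

* The aligner is a simplified heuristic: on hard cases (low homology,
  domain swaps) it can settle below a full TM-align implementation;
  precomputed pairwise TM-scores can be imported instead.
* Reference-pose mode inherits any bias of the chosen reference model; the
  common anchor set shrinks if some model aligns poorly to it.
* Descriptor defaults are conventions, not fitted values; Cα clouds need
  the dedicated preset.
* DBSCAN's singleton-noise convention inflates cluster counts on sparse
  data by design; interpret its k accordingly.
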