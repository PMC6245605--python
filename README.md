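# shapeclust

Shape-based clustering of protein 3D models. Given a directory of PDB
structures — the motivating use case is clonotypic B-cell receptor
immunoglobulin (BcR IG) variable-domain models from leukemia patients, but
any set of single-model structures works — the package discovers groups of
structurally similar models and evaluates them against expert annotation.

Instead of comparing proteins only with bioinformatics similarity scores,
each protein is treated as a 3D point cloud (one point per atom) and
described with local and global shape descriptors from the 3D object
recognition literature:

* **FPFH** — fast point feature histograms of the Darboux-frame angles
  (α, φ, θ) between a point, its normal, and its k nearest neighbors,
  smoothed as FPFH(p) = SPFH(p) + (1/k) Σᵢ SPFH(pᵢ)/dᵢ (33-dimensional).
* **3DSC** — 3D shape context: counts of neighbors in a normal-oriented
  support sphere, binned in azimuth × elevation × log-radius, each point
  weighted by 1/(ρᵢ·V(bin)^⅓).
* **RSD** — radius-based surface descriptor: the (r_min, r_max) of spheres
  through a point and its neighbors consistent with their normals, via the
  chord relation d = r√(2 − 2cos α).
* **VFH** — viewpoint feature histogram: one global vector per cloud
  (centroid-anchored SPFH plus a viewpoint-direction angle histogram).

Pairs of models are first structurally superposed with a TM-score-driven
iterative aligner (Kabsch superposition alternated with dynamic programming
over the score matrix Sᵢⱼ = 1/(1 + (dᵢⱼ/d₀)²), d₀(L) = 1.24·(L−15)^⅓ − 1.8).
Descriptor sets F_i = {f_i1 … f_iL} of two aligned models are compared with
the descriptor-space RMSD

    RMSD(F_i, F_j) = sqrt( (1/L) Σ_k ‖f_ik − f_jk‖² ),

which for a global descriptor (L = 1) is the Euclidean distance. The
per-descriptor distance matrices D_m are min-max normalized and fused as
D = Σ_m w_m D_m, with weights either equal or each descriptor's best average
silhouette width over a range of cluster counts. The final matrix is
clustered with k-medoids (PAM with swap improvement), average-linkage
agglomerative clustering, or DBSCAN; the number of clusters is chosen by
maximizing the average silhouette width s̄, sᵢ = (bᵢ − aᵢ)/max(aᵢ, bᵢ), over
k = 3…25. Accuracy against ground-truth labels is the Rand index
R = (a + b)/C(N,2).

Because real patient-derived models cannot be redistributed, the package
ships a synthetic generator: families of protein-like models that share a
hinge-perturbed template backbone (between-family divergence, default 3 Å)
with per-member Gaussian coordinate noise (default 0.3 Å) and random rigid
motions. The default dataset mirrors an annotated six-subset cohort with
family sizes 38/42/22/12/12/11 (137 models).

## Worked example

`examples/01_simulate_and_cluster.py` simulates two families of eight
60-residue models, builds an FPFH distance matrix on the Cα clouds, and
selects the cluster count by silhouette:

```
simulated 8 models in 2 families
FPFH distance matrix: 8 x 8, mean off-diagonal 53.60
selected k* = 2 (average silhouette 0.415)
Rand index vs ground truth = 1.000
```

k\* = 2 means the silhouette criterion recovered the true number of
families, and Rand 1.0 means every pair of models was grouped exactly as in
the ground-truth labels. `examples/02_descriptor_distances.py` shows the
per-pair workflow (align → extract at shared anchors → descriptor RMSD) and
`examples/03_tm_baseline_and_fusion.py` compares the TM-score baseline
matrix with a silhouette-weighted fusion.

The same workflow is scriptable from the shell:

```bash
shapeclust simulate --out data/ --seed 1
shapeclust distances --input data/ --out mats/ --selection calpha --mode reference
shapeclust cluster --matrix mats/distance_fpfh.tsv --out assign.tsv
shapeclust evaluate --assignments assign.tsv --labels data/labels.tsv
```

or driven end-to-end from a YAML config with `shapeclust run-all`.

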