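"""The TM-score baseline matrix versus fused descriptor matrices.

Builds the bioinformatics baseline (1 - mean TM-score per pair) and a
silhouette-weighted fusion of two descriptor matrices on a small labelled
dataset, then clusters both and compares their accuracy.
"""


from shapeclust import (DescriptorConfig, FamilySpec, LabeledPartition,
                        fuse, generate_dataset, k_medoids, normalize_matrix,
                        pairwise_distance_matrix, rand_index, silhouette,
                        silhouette_weights, tm_distance_matrix)

specs = [FamilySpec("A", 3, template_length=50, seed=0),
         FamilySpec("B", 3, template_length=50, seed=1),
         FamilySpec("C", 3, template_length=50, seed=2)]
models, truth = generate_dataset(specs, global_seed=8)

tm = tm_distance_matrix(models)
cfg = DescriptorConfig.for_calpha()
descriptor_mats = [
    normalize_matrix(pairwise_distance_matrix(
        models, d, cfg, selection="calpha", mode="reference"))
    for d in ("fpfh", "rsd")
]
weights = silhouette_weights(descriptor_mats, k_range=range(2, 6), seed=42)
combined = fuse(descriptor_mats, weights)
print("fusion weights (best average silhouette per descriptor):",
      {n: round(float(w), 3) for n, w in zip(("fpfh", "rsd"), weights.weights)})

for name, matrix in (("tm baseline", tm), ("combined", combined)):
    clustering = k_medoids(matrix, k=3, seed=42)
    r = rand_index(LabeledPartition.from_clustering(clustering), truth)
    s = silhouette(matrix, clustering).average
    print(f"{name}: Rand {r:.3f}, average silhouette {s:.3f}")
print("-> Rand 1.0 means the 3-medoid clustering reproduces the three "
      "simulated families exactly")
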