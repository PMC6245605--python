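"""Simulate two structural families and recover them by descriptor clustering.

Builds a small labelled dataset (two families of protein-like models sharing
a backbone within each family), computes an FPFH descriptor-space distance
matrix on C-alpha clouds, selects the number of clusters by average
silhouette width, and scores the result against the ground truth.
"""


from shapeclust import (DescriptorConfig, FamilySpec, LabeledPartition,
                        generate_dataset, pairwise_distance_matrix, rand_index,
                        select_k)

specs = [FamilySpec("A", 4, template_length=60, seed=0),
         FamilySpec("B", 4, template_length=60, seed=1)]
models, truth = generate_dataset(specs, global_seed=11)
print(f"simulated {len(models)} models in {len(specs)} families")

matrix = pairwise_distance_matrix(
    models, "fpfh", DescriptorConfig.for_calpha(),
    selection="calpha", mode="reference")
print(f"FPFH distance matrix: {matrix.n} x {matrix.n}, "
      f"mean off-diagonal {matrix.off_diagonal().mean():.2f}")

k_star, clustering, profile = select_k(matrix, k_range=range(2, 6), seed=42)
r = rand_index(LabeledPartition.from_clustering(clustering), truth)
print(f"selected k* = {k_star} (average silhouette {profile.average:.3f})")
print(f"Rand index vs ground truth = {r:.3f}")
print("-> 1.0 means every pair of models was grouped exactly as in the "
      "true family labels")
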