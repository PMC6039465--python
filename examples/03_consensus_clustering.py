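"""Consensus k-means clustering of tumor methylomes.

Generates a 30-sample cohort whose myeloid-B and myeloid-T phenotypes carry
distinct methylation signatures, clusters the most variable probes, and
shows that the cophenetic coefficient selects k = 2 and recovers the
phenotype split.
"""

import numpy as np

from mpalkit.cluster import consensus_kmeans, select_variable_probes
from mpalkit.simulate import SimulationDesign, sample_ids, simulate_methylation

design = SimulationDesign(
    n_myeloid_B=15, n_myeloid_T=15, lineage_assignment="aligned", seed=11
)
tumors, _, _ = simulate_methylation(design)
beta = tumors.beta()

top = select_variable_probes(beta, n=min(10_000, beta.shape[0]))
result = consensus_kmeans(beta.subset_probes(top), n_resamples=300, seed=3)

print("cophenetic coefficient by k:")
for k, c in result.cophenetic.items():
    marker = "  <- chosen" if k == result.chosen_k else ""
    print(f"  k={k}: {c:.4f}{marker}")

b_ids, t_ids = sample_ids(design)
labels = dict(zip(result.sample_ids, result.labels[result.chosen_k]))
b_clusters = {labels[s] for s in b_ids}
t_clusters = {labels[s] for s in t_ids}
print(f"\nmyeloid-B samples fall in cluster(s) {b_clusters}, myeloid-T in {t_clusters}")
print(f"mean silhouette width at k={result.chosen_k}: {np.mean(result.silhouette):.3f}")
print(
    "\nA single cluster per phenotype with silhouette near 1 means the"
    "\nresampled co-clustering is essentially deterministic: the two planted"
    "\nmethylation groups are cleanly separable."
)
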