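"""Full subtyping pipeline on the default synthetic two-subtype cohort.

Generates 300 controls and 120 patients (two planted subgroups perturbing
disjoint 4-edge sets), computes per-patient differential networks, keeps
edges significant in at least 14 patients, standardizes, picks k by the
elbow rule, clusters with K-means, and validates the result.
"""

from idpn import PipelineConfig, run_pipeline
from idpn.simulate import default_cohort_spec, generate_cohort

table, truth = generate_cohort(default_cohort_spec(), seed=1)
result = run_pipeline(table, PipelineConfig(seed=1))

print(f"selected edges ({len(result.selected_edges)}):")
for edge in result.selected_edges:
    print(f"  {edge[0]} - {edge[1]}")
print(f"elbow-selected k = {result.cluster_model.k}")
print(f"cluster sizes: {result.cluster_model.cluster_sizes.to_dict()}")
print(f"resubstitution discriminant accuracy = {result.lda['accuracy']:.3f}")
print(f"max VIF among clustering variables = {result.vif['vif'].max():.2f}")
sev = result.severity["clusters"][["cluster", "n", "mean", "median", "q1", "q3"]]
print("severity by cluster (cluster 1 = lower mean by convention):")
print(sev.to_string(index=False))
print(f"severity Welch t p-value = {result.severity['p']:.2e}")
# With the default planted displacements, the 8 selected edges are the 8
# planted ones, k = 2, the clusters recover the planted subgroups, and the
# more perturbed subgroup carries the higher NSSI severity.
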