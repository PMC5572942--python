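"""Generate a synthetic three-group connectome cohort and write it to disk.

The cohort emulates a late-life depression study design: 15 patients with
memory deficits (LLD-MD), 24 with intact memory (LLD-IM) and 30 healthy
controls (HC), each with a 90-node connection-probability matrix, a node
table with voxel counts, covariates and cognitive composites.
"""

from richclubnet import SimulationConfig, generate_cohort, write_cohort

cohort, truth = generate_cohort(SimulationConfig(seed=1))
manifest = write_cohort(cohort, "scratch/example_cohort")

print("group sizes:", cohort.group_counts())
print("planted hub regions (node indices):", truth.hub_nodes.tolist())
print("planted deficit subnetwork:", len(truth.planted_nbs_edges), "edges")
print("manifest written to:", manifest)
# The hub indices are the ground truth the rich-club analysis should rediscover;
# the 20-edge subnetwork is what NBS should flag when comparing LLD-MD vs LLD-IM.
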