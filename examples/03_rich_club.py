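"""Weighted rich-club analysis: curves, region definition, class strengths.

Voxel-normalizes each prevalence-filtered matrix, evaluates the rich-club
coefficient against 200 weight-reshuffle nulls at r = 1/15 .. 14/15, defines
the 12-node rich-club region from the healthy-control group mean, and
partitions edges into rich-club / feeder / local classes on raw weights.
"""

import numpy as np

from richclubnet import AnalysisConfig, SimulationConfig, generate_cohort, run_richclub

cohort, truth = generate_cohort(SimulationConfig(seed=1))
res = run_richclub(cohort, AnalysisConfig(seed=1), n_null=200, n_perm=10000)

print("rich-club region:", ", ".join(res.rich_labels))
overlap = len(set(res.rich_nodes.tolist()) & set(truth.hub_nodes.tolist()))
print(f"planted hubs recovered: {overlap}/12")

for g in ("HC", "LLD-IM", "LLD-MD"):
    vals = [res.curves[s.subject_id].phi_norm[1] for s in cohort.group(g)]
    print(f"{g}: mean phi_norm at r=2/15 = {np.mean(vals):.3f}")
# phi_norm > 1 indicates rich-club organization; the patient groups sit lower
# because their hub-hub weights were generated 20% weaker.

print(res.class_strengths.groupby("group").mean().round(5))
for name, test in res.group_tests.items():
    print(f"{name}: F={test.statistic:.2f}, permutation p={test.p_value:.4g}")
# The adjusted permutation test (age/education/gender covariates) should flag
# the rich-club strength deficit shared by both patient groups and the
# feeder/local deficits specific to the memory-deficit group.
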