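# richclubnet

Weighted rich-club, global-topology and network-based-statistic (NBS)
analysis of structural brain connectomes, together with a synthetic
three-group cohort generator so that every stage of the pipeline can be
exercised, calibrated and power-tested without MRI data.

## Who this is for

Network-neuroscience analyses of diffusion-MRI connectomes routinely ask
three questions about a patient cohort: is the *rich club* — the tendency of
high-strength hub regions to interconnect more strongly than chance —
intact; are global topological properties (path length, efficiency,
strength, assortativity) altered; and is there a specific subnetwork of
edges that differs between groups? `richclubnet` implements that full
workflow for cohorts of symmetric, nonnegative 90-node (AAL-style)
connection-probability matrices, organized into three groups: late-life
depression with memory deficits (LLD-MD), with intact memory (LLD-IM), and
healthy controls (HC).

## The statistics at the core

**Weighted rich-club coefficient.** After removing edges present in fewer
than 20% of a group's subjects, each matrix is voxel-normalized,
`W'_ij = W_ij / [(v_i/GM)(v_j/GM)]`, to cancel the seed/target region-size
bias of probabilistic tractography. Nodes are ranked by connective strength
`k_i = Σ_j w_ij`; at richness level `r` the club is the top `r·N` nodes and

    φ(r) = ω_club / Σ_{l=1..E_club} w_l^rank ,

the club's internal weight over the sum of the `E_club` strongest edge
weights anywhere in the network, so φ ∈ [0, 1]. Normalization against the
mean of weight-reshuffle null networks (same topology, weights permuted over
edges) gives `φ_norm(r) = φ(r) / ⟨φ_random(r)⟩`; `φ_norm > 1` indicates
rich-club organization. With `N = 90` and denominator 15 the curve has 14
levels `r = 1/15 … 14/15`; the rich-club *region* is the 12 strongest nodes
(`r = 2/15`) of the HC group-mean network, and edges are classed as
rich-club (both endpoints in the region), feeder (one), or local (none),
each class summarized by its average strength (total weight / edge count).

**Global topology.** Weighted clustering Cp (geometric-mean triangle form on
raw weights), characteristic path length Lp with edge length `1/w`, global
efficiency `E_glob = ⟨1/L_ij⟩`, fault-tolerant (local) efficiency Eloc
(mean efficiency of each node's neighbor subgraph), connective strength S,
density, strength assortativity r_ω (weight-weighted Pearson correlation of
endpoint strengths across edges), and small-world γ, λ, σ = γ/λ against
degree-preserving Maslov–Sneppen rewired nulls that carry each edge's weight
through the swap.

**NBS.** Edgewise pooled two-sample t on an 80%-prevalence union mask,
one-tailed primary threshold `p < 0.01`, connected components sized by the
sum of t over their edges (intensity `M`), and family-wise error control by
permuting group labels (default 5,000) and comparing each observed `M`
against the null distribution of the largest component,
`p_corr = (1 + #{M_null ≥ M_obs}) / (1 + n_perm)`.

**Group statistics.** Freedman–Lane covariate-adjusted permutation tests
(default 10,000 permutations; age, education, gender), parametric ANCOVA
with LSD post hoc, cognitive z-composites (executive / processing speed /
memory) from a standard neuropsychological battery, the AVLT delayed-recall
memory-deficit rule, HDRS-adjusted partial Pearson correlations with a
Bonferroni /3 reporting rule, and stepwise regression with a forced
covariate.

## Worked example

```python
import numpy as np
from richclubnet import (AnalysisConfig, SimulationConfig,
                         generate_cohort, run_richclub)

cohort, truth = generate_cohort(SimulationConfig(seed=1))
res = run_richclub(cohort, AnalysisConfig(seed=1), n_null=200, n_perm=10000)

for g in ("HC", "LLD-IM", "LLD-MD"):
    vals = [res.curves[s.subject_id].phi_norm[1] for s in cohort.group(g)]
    print(g, round(float(np.mean(vals)), 3))
print(res.group_tests["rich_club_strength"].p_value)
```

prints (seed 1):

```
HC 1.422
LLD-IM 1.208
LLD-MD 1.354
9.999000099990002e-05
```

All three groups show rich-club organization (`φ_norm > 1` at `r = 2/15`),
and the covariate-adjusted permutation test detects the planted rich-club
strength deficit of the patient groups at the smallest p the 10,000-sample
permutation scheme can produce, 1/10001 ≈ 1e-4. The `examples/` directory
holds one short script per capability (simulation, global metrics,
rich-club, NBS, group statistics), each printing the numbers it computes and
a line on what they mean.

A thin CLI wraps the same functions:

```bash
richclubnet simulate --seed 1 --out cohort_dir
richclubnet run-all --seed 1 --cohort cohort_dir/manifest.csv --out results_dir
```

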