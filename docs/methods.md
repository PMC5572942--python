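# Methods notes

This note records the model choices, conventions and numerical decisions
behind `richclubnet`, and what the synthetic generator does and does not
emulate.

## Data model and preprocessing

A connectome is a symmetric, nonnegative, zero-diagonal matrix of connection
probabilities over `N = 90` atlas regions (configurable). Asymmetry up to
1e-9 is symmetrized by averaging (upstream tractography averages the
directed probabilities); anything larger is rejected as a pipeline error
rather than silently fixed. Group *prevalence filtering* zeroes edges
present (weight > 0) in fewer than 20% of a group's subjects; an edge at
exactly 20% is kept — the rule is "fewer than", read literally. The filtered
matrices feed every subsequent stage, including the small-world null
generation.

## Voxel normalization

Probabilistic tractography seeds a fixed number of streamlines per voxel, so
connection probabilities scale with the sizes of the seed and target
regions. The rich-club steps therefore divide each weight by the product of
endpoint voxel fractions, `W'_ij = W_ij / [(v_i/GM)(v_j/GM)]` (`GM` = whole
brain gray-matter voxels). Two points are deliberate:

* **Division, not multiplication.** The typeset source formula is ambiguous;
  only division *removes* the size bias, which is the stated intent.
* **Scope.** Normalization applies only to rich-club coefficient computation
  and rich-club node ranking. Global metrics and edge-class strengths use
  raw weights, so that a few very strong normalized central connections do
  not mask non-central effects.

## Rich-club analysis

* Node ranking uses connective strength with ties broken by ascending node
  index — deterministic and documented; ties essentially never occur on
  continuous weights.
* φ's denominator ranks edge weights over the *whole* network (Opsahl's
  convention), including club-internal edges.
* Levels are `r = k/15`, `k = 1..14` (integer club sizes for N = 90). Levels
  whose club has no internal edges are recorded as undefined, excluded from
  the AUC and group tests with a logged count, never silently dropped.
* Reshuffle nulls permute the weight multiset over the fixed edge set, so
  degree sequence, topology and total weight are exactly preserved; on a
  uniform-weight network every null equals the original and φ_norm ≡ 1.
* The HC group network used for region definition is the arithmetic mean of
  the subjects' normalized, filtered matrices (the alternative — ranking on
  concatenated subject strengths — is not implemented).
* Curve AUC uses the trapezoidal rule on the discrete r grid; a
  left-rectangle dialect (`method="rectangle"`) exists for sensitivity
  checks.
* Rich-club consensus edges require presence in strictly more than 80% of
  subjects ("more than" is strict).

## Global metrics

* **Weight→length mapping is `1/w`** for all shortest-path quantities. The
  magnitudes this produces (Lp tens of units, E_glob ≈ 1/Lp) match the scale
  on which such connectome studies report these quantities. The mapping is
  the package's documented dialect; no alternative transform is provided.
* Clustering uses raw weights without max-weight rescaling; the Cp scale is
  then directly on the probability scale (~1e-3 for probability-weighted
  networks).
* Assortativity correlates endpoint *strengths* (not degrees), weighted by
  edge weight over the symmetric ordered-pair expansion. A network whose
  endpoint strengths carry no variance (uniform complete graph) raises a
  degenerate-metric error instead of returning 0.
* Small-world nulls are Maslov–Sneppen edge swaps (10·E attempts per null)
  carrying each edge's weight with it, preserving the degree sequence and
  the weight multiset. Graphs admitting no swap (complete graphs) yield
  nulls equal to the original, hence γ = λ = σ = 1. Disconnected nulls are
  redrawn up to five times, then skipped with a count; at the densities this
  package targets (~0.64) they do not occur.
* Lp on a disconnected network is an error identifying the components;
  E_glob treats unreachable pairs as zero contribution.

## NBS

Pooled-variance t statistics (the common NBS default; zero-variance edges
are undefined and sub-threshold), one-tailed orientation "group A < group
B", strict `t > t*` membership at the primary threshold, intensity
(sum-of-t) component size, and the `(1+x)/(1+n)` permutation p estimator.
The observed labeling is not recycled as a permutation — the +1 plays that
role — so corrected p is never 0 and never exactly recomputed from the
observed data. Component discovery is breadth-first over edges sharing
nodes.

## Covariate-adjusted permutation tests

The source procedure says only "adjusted for age, education, and gender".
The package uses the Freedman–Lane scheme: regress the outcome on covariates
alone, permute the residuals, re-attach the covariate fit, recompute the
between-group partial F. A simpler residual-permutation dialect
(`scheme="residual"`) is available for comparison. Pairwise follow-up runs
the same scheme per group pair without multiplicity correction (LSD-style),
matching the parametric ANCOVA + LSD path, which is also implemented and
agrees with the permutation test in ≥90% of Gaussian datasets (tested).
Gender enters as a binary indicator. Stepwise regression uses entry p 0.05 /
removal p 0.10 (the common package default) with the forced covariate never
removed.

## Synthetic cohort generator

The generator's defaults define the study conditions: groups of 15/24/30
(LLD-MD / LLD-IM / HC), 90 nodes, 12 planted hubs, edge density 0.64,
log-normal edge weights (log-mean −5.1, log-SD 0.75), hub boost
√3 per hub endpoint (hub–hub edges ×3), subject-level multiplicative
log-noise SD 0.25, covariate means/SDs from the published demographics
tables, and deficits: rich-club ×0.8 in both patient groups, feeder and
local ×0.85 plus a connected 20-edge subnetwork ×0.6 only in the
memory-deficit group. No effect sizes exist on the weight scale in the
source; all deltas are artifact choices fixed once.

Design points worth knowing:

* **Shared skeleton.** Edge topology is drawn once per cohort; subjects
  differ by weight noise. The prevalence filters presuppose largely shared
  topology, and this makes the planted subnetwork present in every subject.
* **Voxel bias is real in the generated data.** Observed weights are
  multiplied by `v_i v_j / mean(v)²`, where region voxel counts are drawn
  once per cohort (atlas anatomy) with 8% log-normal per-subject jitter. The
  voxel normalization step therefore has a genuine bias to remove, and hub
  dominance is only guaranteed on *normalized* strengths — raw strengths can
  be masked by the size bias, exactly the phenomenon motivating the
  normalization.
* **Cognition.** Composites are generated directly as linear loadings on the
  standardized rich-club/feeder/local average strengths plus Gaussian noise
  (SD 0.9), giving correlations of roughly the magnitude such studies
  report. A separate raw-score generator produces plausible test batteries
  for the composite constructor's own tests. Because the three class
  strengths are strongly inter-correlated, stepwise selection can retain a
  correlated proxy for the generating predictor — an inherent property of
  stepwise procedures, visible in the examples.
* **What it does not emulate.** No anatomical geometry, no streamline
  counts, no lattice-like cortical neighborhood structure. The skeleton is
  an Erdős–Rényi-style random graph, so the generated networks are *not*
  strongly small-world (γ only mildly above 1, σ can sit below 1); the
  small-world code is validated instead on ring-lattice constructions and
  exact identities. Likewise assortativity of the generated networks is near
  zero rather than the ~0.3 of real cortical networks. Passing tests
  demonstrate correctness of the estimators and calibration of the
  inference, not realism of every topological feature of real data.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on 100 random graphs of 4–8 nodes against
pure-python enumeration (all simple paths, triple loops, exhaustive weight
permutations). Calibration uses 500 replicates × 200 permutations for the
adjusted permutation test and 200 replicates × 500 permutations for NBS
family-wise error; recovery uses 25 replicates with 1,000–10,000
permutations; per-subject rich-club curves in the acceptance script use 200
reshuffle nulls and the small-world panel 20 rewired nulls over 10 subjects.
These are the package's documented default verification sizes; the
full-scale defaults (1,000 nulls, 5,000–10,000 permutations) remain the
analysis defaults in `AnalysisConfig`.

## Known limitations

* The AVLT delayed-recall norm table ships with only the published 50–59y
  stratum; other ages require a user-supplied table (a missing stratum is an
  error, never a silent default).
* The NBS significant component under the default planted deficit is much
  larger than the 20 planted edges, because the diffuse feeder/local deficit
  of the memory-deficit group contributes suprathreshold edges that connect
  to the planted subnetwork; recovery is measured as planted-edge coverage.
* Permutation p-values are lower-bounded at `1/(n_perm+1)`.
* `ancova_lsd` assumes homogeneous slopes (no group × covariate
  interaction), as standard ANCOVA does.
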