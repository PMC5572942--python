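"""Synthetic three-group connectome cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised without MRI data:

* a shared edge skeleton per cohort (the prevalence filters presuppose
  largely shared topology) with log-normal edge weights;
* a planted hub set whose edges are boosted (sqrt(hub_gain) per hub
  endpoint, i.e. hub-hub edges x hub_gain), yielding rich-club organization;
* a tractography-style voxel-size bias: each observed weight is multiplied
  by v_i v_j / mean(v)^2, which the rich-club voxel normalization removes;
* group deficits: rich-club (hub-hub) edges scaled down in both patient
  groups, feeder/local edges and a planted connected 20-edge subnetwork
  scaled down only in the memory-deficit group;
* covariates drawn to the published group means/SDs (no planted gender
  effect: it exists to exercise covariate adjustment);
* cognitive composites generated as linear loadings on the standardized
  rich-club / feeder / local average strengths plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import derive_rng
from .errors import ValidationError
from .io import (
    GROUPS,
    AnalysisConfig,
    Cohort,
    ConnectivityMatrix,
    NodeTable,
    SubjectRecord,
)
from .rich_club import partition_and_strengths

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort", "plant_effects",
           "generate_raw_scores"]

#: group -> (age_mean, age_sd, edu_mean, edu_sd, hrsd_mean, hrsd_sd, male_frac)
_DEFAULT_COVARIATES = {
    "LLD-MD": (64.47, 6.87, 8.53, 3.76, 9.13, 7.92, 3 / 15),
    "LLD-IM": (66.21, 5.57, 9.71, 3.82, 10.79, 7.11, 6 / 24),
    "HC": (66.23, 4.95, 10.65, 3.00, 1.27, 3.04, 6 / 30),
}

#: domain -> loadings on standardized (rich_club, feeder, local) strengths,
#: mirroring the association pattern the analysis is meant to detect.
_DEFAULT_LOADINGS = {
    "executive": (0.0, 0.5, 0.0),
    "speed": (0.3, 0.0, 0.5),
    "memory": (0.0, 0.0, 0.5),
}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults define the study conditions."""

    n_per_group: tuple = (15, 24, 30)          # (LLD-MD, LLD-IM, HC)
    n_nodes: int = 90
    n_hubs: int = 12
    base_weight_logmean: float = -5.1          # log of a typical edge probability
    base_weight_logsd: float = 0.75
    hub_gain: float = 3.0                      # hub-hub multiplier; feeder gets sqrt
    edge_density: float = 0.64
    delta_richclub: float = 0.8                # both patient groups
    delta_feeder: float = 0.85                 # memory-deficit group only
    delta_local: float = 0.85                  # memory-deficit group only
    nbs_n_edges: int = 20
    nbs_deficit: float = 0.6                   # planted subnetwork, MD group only
    noise_sd: float = 0.25                     # subject-level multiplicative log-noise
    covariate_stats: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    cognition_loadings: dict = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    cognition_noise_sd: float = 0.9
    voxel_count_range: tuple = (200, 4000)
    voxel_jitter_sd: float = 0.08              # per-subject log-normal size jitter
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_hubs < self.n_nodes:
            raise ValidationError("need 2 <= n_hubs < n_nodes")
        if not 0 < self.edge_density <= 1:
            raise ValidationError("edge_density must lie in (0,1]")
        for name in ("hub_gain", "delta_richclub", "delta_feeder", "delta_local",
                     "nbs_deficit"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    hub_nodes: np.ndarray
    planted_nbs_edges: list                 # unordered (i, j) pairs
    deltas: dict                            # group -> class multipliers applied
    cognition_loadings: dict
    skeleton_mask: np.ndarray               # boolean adjacency of present edges


def _edge_classes(n: int, hubs: np.ndarray):
    """Boolean triu masks (rich, feeder, local) given the hub set."""
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    iu, ju = np.triu_indices(n, k=1)
    n_hub_ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    return iu, ju, n_hub_ends


def _connected_skeleton(n: int, p: float, rng) -> np.ndarray:
    """Symmetric boolean adjacency with density ~p, forced connected."""
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < p
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[present], ju[present]] = True
    adj |= adj.T
    # connect any stray components through random bridges (rare at p >= 0.1)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    while True:
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)
        if ncomp == 1:
            break
        a = rng.choice(np.flatnonzero(labels == 0))
        b = rng.choice(np.flatnonzero(labels != 0))
        adj[a, b] = adj[b, a] = True
    return adj


def _plant_connected_subnetwork(adj: np.ndarray, hubs: np.ndarray, n_edges: int,
                                rng) -> list:
    """A connected set of ``n_edges`` skeleton edges grown from a non-hub seed.

    Mirrors the study's deficit subnetwork: one connected component, touching
    mostly non-hub (feeder/local) territory.
    """
    n = adj.shape[0]
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True
    non_hubs = np.flatnonzero(~is_hub)
    start = int(rng.choice(non_hubs))
    visited = {start}
    edges: list = []
    frontier = [start]
    while len(edges) < n_edges and frontier:
        node = frontier[rng.integers(len(frontier))]
        nbrs = np.flatnonzero(adj[node])
        # prefer expanding into non-hub territory, as in the observed deficit
        order = nbrs[np.argsort(is_hub[nbrs] + rng.random(len(nbrs)))]
        grown = False
        for nxt in order:
            e = (min(node, int(nxt)), max(node, int(nxt)))
            if e not in edges:
                edges.append(e)
                if int(nxt) not in visited:
                    visited.add(int(nxt))
                    frontier.append(int(nxt))
                grown = True
                break
        if not grown:
            frontier.remove(node)
    if len(edges) < n_edges:
        raise ValidationError("skeleton too sparse to plant the deficit subnetwork")
    return edges


def plant_effects(base_matrix, group: str, cfg: SimulationConfig,
                  truth: GroundTruth) -> ConnectivityMatrix:
    """Apply the group-specific multiplicative deficits to a template matrix.

    HC matrices pass through unchanged. Both patient groups scale hub-hub
    (rich-club) edges by ``delta_richclub``; the memory-deficit group
    additionally scales feeder and local edges by their deltas and the
    planted subnetwork edges by ``nbs_deficit``. Symmetry is preserved.
    """
    w = np.array(base_matrix.weights if isinstance(base_matrix, ConnectivityMatrix)
                 else base_matrix, dtype=float)
    if group == "HC":
        return ConnectivityMatrix(w)
    n = w.shape[0]
    iu, ju, n_hub_ends = _edge_classes(n, truth.hub_nodes)
    factors = np.ones(len(iu))
    factors[n_hub_ends == 2] *= cfg.delta_richclub
    if group == "LLD-MD":
        factors[n_hub_ends == 1] *= cfg.delta_feeder
        factors[n_hub_ends == 0] *= cfg.delta_local
        planted = set(truth.planted_nbs_edges)
        planted_mask = np.array([(int(a), int(b)) in planted for a, b in zip(iu, ju)])
        factors[planted_mask] *= cfg.nbs_deficit
    w[iu, ju] *= factors
    w[ju, iu] = w[iu, ju]
    return ConnectivityMatrix(w)


def _aal_style_labels(n: int) -> list[str]:
    side = ("L", "R")
    return [f"Region_{i // 2 + 1:02d}.{side[i % 2]}" for i in range(n)]


def generate_cohort(cfg: SimulationConfig | None = None) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort and its ground truth; deterministic given cfg.seed."""
    cfg = cfg or SimulationConfig()
    rng = derive_rng(cfg.seed, "generate_cohort")
    n = cfg.n_nodes

    hubs = np.sort(rng.choice(n, size=cfg.n_hubs, replace=False))
    adj = _connected_skeleton(n, cfg.edge_density, rng)
    iu, ju, n_hub_ends_all = _edge_classes(n, hubs)
    present = adj[iu, ju]
    ei, ej = iu[present], ju[present]
    n_hub_ends = n_hub_ends_all[present]

    base = rng.lognormal(cfg.base_weight_logmean, cfg.base_weight_logsd, size=len(ei))
    base *= np.sqrt(cfg.hub_gain) ** n_hub_ends

    planted = _plant_connected_subnetwork(adj, hubs, cfg.nbs_n_edges, rng)
    truth = GroundTruth(
        hub_nodes=hubs,
        planted_nbs_edges=planted,
        deltas={
            "HC": {},
            "LLD-IM": {"rich_club": cfg.delta_richclub},
            "LLD-MD": {"rich_club": cfg.delta_richclub, "feeder": cfg.delta_feeder,
                       "local": cfg.delta_local, "nbs": cfg.nbs_deficit},
        },
        cognition_loadings=dict(cfg.cognition_loadings),
        skeleton_mask=adj,
    )

    labels = _aal_style_labels(n)
    subjects: list[SubjectRecord] = []
    class_strengths: list[tuple[float, float, float]] = []
    lo, hi = cfg.voxel_count_range
    # atlas region sizes are anatomical: one base draw per cohort, small
    # per-subject jitter, so the voxel bias is nearly common across subjects
    base_voxels = rng.integers(lo, hi + 1, size=n)
    for group, n_group in zip(GROUPS, cfg.n_per_group):
        a_mean, a_sd, e_mean, e_sd, h_mean, h_sd, male_frac = cfg.covariate_stats[group]
        for s_i in range(n_group):
            sid = f"{group}-{s_i + 1:03d}"
            srng = derive_rng(cfg.seed, "subject", sid)
            noise = np.exp(srng.normal(0.0, cfg.noise_sd, size=len(ei)))
            w = np.zeros((n, n))
            w[ei, ej] = base * noise
            w[ej, ei] = w[ei, ej]
            m = plant_effects(w, group, cfg, truth)

            # class strengths on the bias-free matrix drive the cognition model
            part = partition_and_strengths(m, hubs)
            class_strengths.append(tuple(part.class_average_strength[c]
                                         for c in ("rich_club", "feeder", "local")))

            voxels = np.clip(
                np.round(base_voxels * np.exp(
                    srng.normal(0.0, cfg.voxel_jitter_sd, size=n))).astype(int),
                lo, hi)
            gm_total = int(np.ceil(voxels.sum() * srng.uniform(1.15, 1.35)))
            bias = voxels / voxels.mean()
            observed = m.weights * np.outer(bias, bias)
            np.fill_diagonal(observed, 0.0)

            nodes = NodeTable(
                pd.DataFrame({
                    "label": labels,
                    "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n)],
                    "voxel_count": voxels,
                }),
                gray_matter_total=gm_total,
            )
            age = float(np.clip(srng.normal(a_mean, a_sd), 55.0, 90.0))
            edu = float(np.clip(srng.normal(e_mean, e_sd), 1.0, 22.0))
            hrsd = int(np.clip(round(srng.normal(h_mean, h_sd)), 0, 52))
            gender = "M" if srng.random() < male_frac else "F"
            subjects.append(SubjectRecord(
                subject_id=sid, group=group, age=age, education=edu,
                gender=gender, hrsd=hrsd,
                matrix=ConnectivityMatrix(observed), nodes=nodes,
            ))

    # cognition: loadings on standardized class strengths + noise
    strengths = np.array(class_strengths)
    z = (strengths - strengths.mean(axis=0)) / strengths.std(axis=0, ddof=1)
    crng = derive_rng(cfg.seed, "cognition")
    for k, subj in enumerate(subjects):
        subj.cognition = {
            domain: float(np.dot(load, z[k]) + crng.normal(0.0, cfg.cognition_noise_sd))
            for domain, load in cfg.cognition_loadings.items()
        }

    cohort = Cohort(subjects, AnalysisConfig(seed=cfg.seed))
    return cohort, truth


def generate_raw_scores(groups, seed: int = 0) -> pd.DataFrame:
    """Plausible raw neuropsychological scores per subject for composite tests.

    Group means track the published battery pattern (memory-deficit patients
    score worst, controls best); this feeds the composite constructor's own
    tests and is independent of the connectome generator.
    """
    rng = derive_rng(seed, "raw_scores")
    #                      MD      IM      HC
    means = {
        "mmse": (21.4, 26.5, 27.4), "avlt": (3.0, 6.5, 7.3), "lmt": (6.0, 10.0, 11.0),
        "tmt_a": (90.0, 70.0, 60.0), "tmt_b": (220.0, 170.0, 150.0),
        "stroop_a": (35.0, 28.0, 25.0), "stroop_c": (90.0, 70.0, 62.0),
        "dst_forward": (7.0, 8.0, 8.0), "dst_backward": (3.5, 4.5, 5.0),
        "sdmt": (20.0, 30.0, 35.0),
    }
    gi = {g: k for k, g in enumerate(GROUPS)}
    rows = []
    for g in groups:
        k = gi[g]
        row = {
            "mmse": np.clip(rng.normal(means["mmse"][k], 2.5), 0, 30),
            "tmt_a": max(10, rng.normal(means["tmt_a"][k], 20)),
            "tmt_b": max(20, rng.normal(means["tmt_b"][k], 45)),
            "stroop_a": max(10, rng.normal(means["stroop_a"][k], 6)),
            "stroop_c": max(15, rng.normal(means["stroop_c"][k], 15)),
            "dst_forward": np.clip(rng.normal(means["dst_forward"][k], 1.2), 2, 12),
            "dst_backward": np.clip(rng.normal(means["dst_backward"][k], 1.2), 1, 10),
            "sdmt": np.clip(rng.normal(means["sdmt"][k], 7), 0, 80),
            "lmt": np.clip(rng.normal(means["lmt"][k], 2.5), 0, 25),
        }
        for trial in range(1, 6):
            row[f"avlt_n{trial}"] = np.clip(
                rng.normal(means["avlt"][k] + 0.3 * (trial - 3), 1.8), 0, 15)
        rows.append(row)
    return pd.DataFrame(rows)
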