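"""High-level orchestration of the full analysis on a cohort.

Order of operations mirrors the methods: per-group prevalence filtering,
voxel normalization (rich-club steps only), rich-club curves against
reshuffle nulls, rich-club region definition from the healthy controls,
edge-class strengths on raw weights, global metrics, NBS between the two
patient groups, and covariate-adjusted group statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_metrics import apply_prevalence_filter, compute_global_metrics
from .group_stats import GroupTestResult, adjusted_permutation_test
from .io import GROUPS, AnalysisConfig, Cohort
from .nbs import NBSResult, nbs_permutation
from .rich_club import (
    RichClubCurve,
    curve_auc,
    define_rich_club_nodes,
    normalized_curve,
    partition_and_strengths,
    voxel_normalize,
)

__all__ = ["RichClubAnalysis", "run_richclub", "run_metrics", "run_nbs",
           "covariate_frame", "group_label_array"]


@dataclass
class RichClubAnalysis:
    rich_nodes: np.ndarray
    rich_labels: list
    curves: dict                      # subject_id -> RichClubCurve
    auc: dict                         # subject_id -> float
    class_strengths: pd.DataFrame     # rows subjects; rich_club/feeder/local columns
    r_define: float
    group_tests: dict = field(default_factory=dict)   # quantity -> GroupTestResult


def _filtered_by_group(cohort: Cohort, cfg: AnalysisConfig) -> dict:
    out = {}
    for g in GROUPS:
        subjects = cohort.group(g)
        if not subjects:
            continue
        filt, mask = apply_prevalence_filter(
            [s.matrix for s in subjects], cfg.prevalence_keep_threshold)
        out[g] = (subjects, filt, mask)
    return out


def covariate_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame({
        "age": [s.age for s in cohort.subjects],
        "education": [s.education for s in cohort.subjects],
        "gender": [s.gender for s in cohort.subjects],
    })


def group_label_array(cohort: Cohort) -> np.ndarray:
    return np.array([s.group for s in cohort.subjects])


def run_richclub(cohort: Cohort, cfg: AnalysisConfig | None = None,
                 n_null: int | None = None, with_group_tests: bool = True,
                 n_perm: int | None = None) -> RichClubAnalysis:
    """Rich-club curves, region definition, class strengths and group tests."""
    cfg = cfg or cohort.config
    n_null = cfg.n_null_richclub if n_null is None else n_null
    n_perm = cfg.n_perm_group if n_perm is None else n_perm
    by_group = _filtered_by_group(cohort, cfg)

    normalized = {}
    raw_filtered = {}
    for g, (subjects, filt, _mask) in by_group.items():
        for s, fm in zip(subjects, filt):
            normalized[s.subject_id] = voxel_normalize(fm, s.nodes)
            raw_filtered[s.subject_id] = fm

    r_define = 2.0 / cfg.richness_denominator
    hc_subjects = cohort.group("HC")
    hc_norm = [normalized[s.subject_id] for s in hc_subjects]
    node_table = cohort.subjects[0].nodes
    rich_nodes, rich_labels = define_rich_club_nodes(hc_norm, node_table, r_define)

    curves, auc = {}, {}
    for s in cohort.subjects:
        sub_seed = cfg.seed + zlib.crc32(s.subject_id.encode()) % 100000
        curve = normalized_curve(normalized[s.subject_id], cfg, n_null=n_null,
                                 seed=sub_seed)
        curves[s.subject_id] = curve
        auc[s.subject_id] = curve_auc(curve)

    rows = []
    for s in cohort.subjects:
        part = partition_and_strengths(raw_filtered[s.subject_id], rich_nodes)
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     **part.class_average_strength})
    strengths = pd.DataFrame(rows).set_index("subject_id")

    analysis = RichClubAnalysis(rich_nodes=rich_nodes, rich_labels=rich_labels,
                                curves=curves, auc=auc, class_strengths=strengths,
                                r_define=r_define)
    if with_group_tests and all(len(cohort.group(g)) >= 2 for g in GROUPS):
        cov = covariate_frame(cohort)
        labels = group_label_array(cohort)
        level_idx = int(round(r_define * cfg.richness_denominator)) - 1
        phi_norm_at_define = np.array(
            [curves[s.subject_id].phi_norm[level_idx] for s in cohort.subjects])
        analysis.group_tests["phi_norm_at_r_define"] = adjusted_permutation_test(
            phi_norm_at_define, labels, cov, n_perm=n_perm, seed=cfg.seed)
        analysis.group_tests["auc"] = adjusted_permutation_test(
            np.array([auc[s.subject_id] for s in cohort.subjects]), labels, cov,
            n_perm=n_perm, seed=cfg.seed + 1)
        for cls in ("rich_club", "feeder", "local"):
            analysis.group_tests[f"{cls}_strength"] = adjusted_permutation_test(
                strengths[cls].to_numpy(), labels, cov, n_perm=n_perm,
                seed=cfg.seed + 2)
    return analysis


def run_metrics(cohort: Cohort, cfg: AnalysisConfig | None = None,
                with_small_world: bool = False,
                n_null_smallworld: int | None = None) -> pd.DataFrame:
    """Per-subject global metrics on the group-prevalence-filtered matrices."""
    cfg = cfg or cohort.config
    if n_null_smallworld is not None:
        import dataclasses
        cfg = dataclasses.replace(cfg, n_null_smallworld=n_null_smallworld)
    by_group = _filtered_by_group(cohort, cfg)
    rows = []
    for g, (subjects, filt, _mask) in by_group.items():
        for s, fm in zip(subjects, filt):
            gm = compute_global_metrics(fm, cfg, with_small_world=with_small_world)
            rows.append({"subject_id": s.subject_id, "group": g, "cp": gm.cp,
                         "lp": gm.lp, "s": gm.s, "e_glob": gm.e_glob,
                         "e_loc": gm.e_loc, "r_assort": gm.r_assort,
                         "density": gm.density, "gamma": gm.gamma, "lam": gm.lam,
                         "sigma": gm.sigma})
    return pd.DataFrame(rows).set_index("subject_id")


def run_nbs(cohort: Cohort, cfg: AnalysisConfig | None = None,
            group_a: str = "LLD-MD", group_b: str = "LLD-IM",
            n_perm: int | None = None, tail: str = "a_less_b") -> NBSResult:
    """NBS between two groups on raw matrices (the mask handles prevalence)."""
    cfg = cfg or cohort.config
    return nbs_permutation(cohort.matrices(group_a), cohort.matrices(group_b),
                           cfg, tail=tail, n_perm=n_perm)
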