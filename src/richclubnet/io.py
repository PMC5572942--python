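"""Containers and delimited-text I/O for connectome cohorts.

The on-disk layout is deliberately plain: one square CSV/TSV per subject
(connection-probability matrix), one CSV node table per subject (AAL-style
labels, hemisphere, voxel counts, whole-brain gray-matter voxel total), and a
single cohort manifest CSV tying subjects, group labels, covariates, raw
neuropsychological scores and file references together.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The three study groups: late-life depression with memory deficits, with
#: intact memory, and healthy controls.
GROUPS = ("LLD-MD", "LLD-IM", "HC")

#: Raw neuropsychological test battery column names used by the composite
#: constructor. Times are completion times (s), other scores are counts.
RAW_TEST_NAMES = (
    "mmse",
    "avlt_n1",
    "avlt_n2",
    "avlt_n3",
    "avlt_n4",
    "avlt_n5",
    "tmt_a",
    "tmt_b",
    "stroop_a",
    "stroop_c",
    "dst_forward",
    "dst_backward",
    "sdmt",
    "lmt",
)

_SYMMETRY_TOL = 1e-9


def _as_weights(m) -> np.ndarray:
    """Accept a ConnectivityMatrix or bare array; return the weight array."""
    if isinstance(m, ConnectivityMatrix):
        return m.weights
    return np.asarray(m, dtype=float)


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over ``n_nodes`` regions.

    Entries are connection probabilities (unitless). The diagonal is zero and
    the matrix is symmetric because the upstream tractography averages the
    i->j and j->i probabilities.
    """

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got shape {w.shape}")
        if np.any(w < 0):
            raise ValidationError("connectivity matrix has negative entries")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL:g}; "
                "the upstream pipeline must average the ij/ji weights"
            )
        w = (w + w.T) / 2.0  # idempotent for already-symmetric input
        if np.any(np.diag(w) != 0):
            logger.warning("nonzero diagonal forced to 0 in connectivity matrix")
            np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class NodeTable:
    """Per-node atlas info plus the subject's whole-brain gray-matter total.

    ``table`` has columns ``label`` (unique AAL region name), ``hemisphere``
    ("left"/"right") and ``voxel_count`` (2 mm isotropic voxels, >= 1).
    """

    table: pd.DataFrame
    gray_matter_total: int

    def __post_init__(self):
        df = self.table.reset_index(drop=True)
        required = {"label", "hemisphere", "voxel_count"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"node table missing columns: {sorted(missing)}")
        if df["label"].duplicated().any():
            raise ValidationError("node labels must be unique")
        if (df["voxel_count"] < 1).any():
            raise ValidationError("voxel counts must be >= 1")
        if self.gray_matter_total < int(df["voxel_count"].max()):
            raise ValidationError("gray_matter_total must be >= max voxel_count")
        self.table = df

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def voxel_counts(self) -> np.ndarray:
        return self.table["voxel_count"].to_numpy(dtype=float)


@dataclass
class SubjectRecord:
    """One subject: group membership, covariates, scores, and their network."""

    subject_id: str
    group: str
    age: float
    education: float
    gender: str
    hrsd: int
    matrix: ConnectivityMatrix
    nodes: NodeTable
    raw_tests: dict | None = None
    cognition: dict | None = None  # executive / speed / memory composites
    matrix_ref: str | None = None
    node_table_ref: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if not self.age > 0:
            raise ValidationError(f"subject {self.subject_id!r}: age must be > 0")


@dataclass
class AnalysisConfig:
    """Tunable thresholds, null/permutation counts and the master seed."""

    prevalence_keep_threshold: float = 0.20
    nbs_mask_threshold: float = 0.80
    richclub_edge_threshold: float = 0.80
    richness_denominator: int = 15
    n_null_richclub: int = 1000
    n_null_smallworld: int = 1000
    n_perm_group: int = 10000
    n_perm_nbs: int = 5000
    nbs_primary_p: float = 0.01
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("prevalence_keep_threshold", "nbs_mask_threshold",
                     "richclub_edge_threshold", "nbs_primary_p", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0,1), got {v}")
        for name in ("richness_denominator", "n_null_richclub", "n_null_smallworld",
                     "n_perm_group", "n_perm_nbs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """All subjects of a study plus the analysis configuration."""

    subjects: list[SubjectRecord]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        seen = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
        sizes = {s.matrix.n_nodes for s in self.subjects}
        if len(sizes) > 1:
            raise ValidationError(f"subjects disagree on n_nodes: {sorted(sizes)}")

    def group(self, label: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == label]

    def matrices(self, label: str | None = None) -> list[ConnectivityMatrix]:
        subjects = self.subjects if label is None else self.group(label)
        return [s.matrix for s in subjects]

    def group_counts(self) -> dict:
        return {g: len(self.group(g)) for g in GROUPS}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _delimiter_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path, n_nodes: int = 90) -> ConnectivityMatrix:
    """Read an ``n_nodes`` x ``n_nodes`` delimited text matrix.

    CSV vs TSV is decided by the file extension. Asymmetry within 1e-9 is
    symmetrized by averaging; larger asymmetry, negative entries and wrong
    shapes are rejected.
    """
    try:
        w = np.loadtxt(path, delimiter=_delimiter_for(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if w.shape != (n_nodes, n_nodes):
        raise FormatError(
            f"matrix file {path} has shape {w.shape}, expected ({n_nodes}, {n_nodes})"
        )
    return ConnectivityMatrix(w)


def read_node_table(path) -> NodeTable:
    """Read a node table CSV (label, hemisphere, voxel_count, gray_matter_total)."""
    df = pd.read_csv(path)
    if "gray_matter_total" not in df.columns:
        raise FormatError(f"node table {path} lacks a gray_matter_total column")
    gm = df["gray_matter_total"].to_numpy()
    if len(set(gm.tolist())) != 1:
        raise ValidationError(f"node table {path}: gray_matter_total must be constant")
    return NodeTable(df.drop(columns=["gray_matter_total"]), int(gm[0]))


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort manifest CSV and every referenced matrix / node table.

    Missing test scores (empty cells) are loaded as NaN markers, never dropped.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    subjects = []
    for idx, row in df.iterrows():
        group = row["group"]
        if group not in GROUPS:
            raise ValidationError(
                f"manifest row {idx} (subject {row['subject_id']!r}): "
                f"unknown group label {group!r}"
            )
        mpath = base / row["matrix_path"]
        npath = base / row["node_table_path"]
        nodes = read_node_table(npath)
        matrix = read_matrix(mpath, n_nodes=nodes.n_nodes)
        raw = {}
        for name in RAW_TEST_NAMES:
            col = f"test_{name}"
            if col in df.columns:
                raw[name] = float(row[col]) if pd.notna(row[col]) else np.nan
        cognition = None
        comp_cols = [c for c in df.columns if c.startswith("comp_")]
        if comp_cols:
            cognition = {c[len("comp_"):]: float(row[c]) for c in comp_cols}
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                age=float(row["age"]),
                education=float(row["education"]),
                gender=str(row["gender"]),
                hrsd=int(row["hrsd"]),
                matrix=matrix,
                nodes=nodes,
                raw_tests=raw or None,
                cognition=cognition,
                matrix_ref=str(row["matrix_path"]),
                node_table_ref=str(row["node_table_path"]),
            )
        )
    return Cohort(subjects)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_MATRIX_FMT = "%.17g"  # full double precision so round-trips are bit-identical


def write_matrix(m, path) -> None:
    np.savetxt(path, _as_weights(m), delimiter=_delimiter_for(path), fmt=_MATRIX_FMT)


def write_node_table(nodes: NodeTable, path) -> None:
    df = nodes.table.copy()
    df["gray_matter_total"] = nodes.gray_matter_total
    df.to_csv(path, index=False)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write matrices, node tables and the manifest; return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "matrices").mkdir(exist_ok=True)
    rows = []
    for s in cohort.subjects:
        mrel = f"matrices/{s.subject_id}_matrix.csv"
        nrel = f"matrices/{s.subject_id}_nodes.csv"
        write_matrix(s.matrix, out_dir / mrel)
        write_node_table(s.nodes, out_dir / nrel)
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "education": s.education,
            "gender": s.gender,
            "hrsd": s.hrsd,
            "matrix_path": mrel,
            "node_table_path": nrel,
        }
        if s.raw_tests:
            row.update({f"test_{k}": v for k, v in s.raw_tests.items()})
        if s.cognition:
            row.update({f"comp_{k}": v for k, v in s.cognition.items()})
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_metrics_table(metrics_by_subject: Mapping[str, "object"], path) -> None:
    """One row per subject, one column per global metric."""
    rows = []
    for sid, gm in metrics_by_subject.items():
        d = dataclasses.asdict(gm) if dataclasses.is_dataclass(gm) else dict(gm)
        rows.append({"subject_id": sid, **d})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_table(curve, path) -> None:
    """Rich-club curve as rows of (r, phi, phi_random_mean, phi_norm)."""
    pd.DataFrame(
        {
            "r": curve.levels,
            "phi": curve.phi,
            "phi_random_mean": curve.phi_random_mean,
            "phi_norm": curve.phi_norm,
        }
    ).to_csv(path, index=False, float_format=_MATRIX_FMT)


def read_curve_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_nbs_edges(result, labels: Sequence[str], path) -> None:
    """NBS component edges with AAL text labels, never bare indices."""
    rows = []
    for cid, comp in enumerate(result.components):
        for (i, j) in comp.edges:
            rows.append(
                {
                    "node_i_label": labels[i],
                    "node_j_label": labels[j],
                    "t_value": result.t_of_edge(i, j),
                    "component_id": cid,
                }
            )
    pd.DataFrame(rows, columns=["node_i_label", "node_j_label", "t_value",
                                "component_id"]).to_csv(path, index=False)


def write_summary(config: AnalysisConfig, out_dir, extra: dict | None = None) -> Path:
    """Run summary JSON: config, seed and software version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.to_dict(), "seed": config.seed, "version": __version__}
    if extra:
        payload.update(extra)
    path = out_dir / "run_summary.json"
    path.write_text(json.dumps(payload, indent=2, default=float))
    return path


def write_results(results, out_dir, *, labels: Sequence[str] | None = None,
                  config: AnalysisConfig | None = None) -> list[Path]:
    """Dispatch on the result type and write the matching delimited table(s)."""
    from .nbs import NBSResult
    from .rich_club import RichClubCurve

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(results, RichClubCurve):
        p = out_dir / "richclub_curve.csv"
        write_curve_table(results, p)
        written.append(p)
    elif isinstance(results, NBSResult):
        if labels is None:
            raise ValidationError("writing an NBS result requires node labels")
        p = out_dir / "nbs_edges.csv"
        write_nbs_edges(results, labels, p)
        written.append(p)
    elif isinstance(results, Mapping):
        p = out_dir / "global_metrics.csv"
        write_metrics_table(results, p)
        written.append(p)
    else:
        raise FormatError(f"do not know how to write results of type {type(results)!r}")
    if config is not None:
        written.append(write_summary(config, out_dir))
    return written
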