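"""Network-based statistic (NBS) for two-group edgewise comparisons.

Edgewise two-sample t statistics are computed on a prevalence mask, edges
exceeding the one-tailed critical value at the primary threshold form a
suprathreshold graph, connected components are sized by the *sum of t* over
their edges (intensity), and family-wise error is controlled by comparing
each observed component against the permutation distribution of the largest
component size under random relabeling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seeding import derive_rng
from .errors import ValidationError
from .io import AnalysisConfig, _as_weights

__all__ = [
    "Component",
    "NBSResult",
    "nbs_mask",
    "edgewise_t",
    "suprathreshold_components",
    "nbs_permutation",
]


@dataclass
class Component:
    """A connected suprathreshold component with its intensity size M."""

    edges: list            # list of unordered (i, j) pairs
    nodes: set
    m: float               # sum of edgewise t over the component


@dataclass
class NBSResult:
    mask: np.ndarray                   # boolean adjacency of tested edges
    t_map: np.ndarray                  # symmetric matrix of t values (nan off-mask)
    primary_t_threshold: float
    components: list = field(default_factory=list)
    null_max_sizes: np.ndarray | None = None
    corrected_p: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> list:
        if self.corrected_p is None:
            return []
        return [c for c, p in zip(self.components, self.corrected_p) if p < self.alpha]

    def t_of_edge(self, i: int, j: int) -> float:
        return float(self.t_map[i, j])


def nbs_mask(group_a, group_b, threshold: float = 0.80) -> np.ndarray:
    """Edges present in >= ``threshold`` of group A subjects OR of group B subjects."""
    wa = [_as_weights(m) for m in group_a]
    wb = [_as_weights(m) for m in group_b]
    if not wa or not wb:
        raise ValidationError("both groups must be nonempty")
    pa = np.mean([w > 0 for w in wa], axis=0)
    pb = np.mean([w > 0 for w in wb], axis=0)
    mask = (pa >= threshold) | (pb >= threshold)
    np.fill_diagonal(mask, False)
    return mask


def _stack_edges(ws: list[np.ndarray], iu, ju) -> np.ndarray:
    return np.stack([w[iu, ju] for w in ws])


def _t_stats(xa: np.ndarray, xb: np.ndarray, tail: str) -> np.ndarray:
    """Pooled-variance two-sample t per edge column; NaN where pooled SD is 0.

    Oriented so positive t supports the one-tailed alternative A < B when
    tail == "a_less_b"; "two_sided" keeps the same orientation and the caller
    thresholds on |t|.
    """
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[sp2 <= 0] = np.nan
    if tail not in ("a_less_b", "two_sided"):
        raise ValidationError(f"unknown tail {tail!r}")
    return t


def edgewise_t(group_a, group_b, mask: np.ndarray, tail: str = "a_less_b") -> np.ndarray:
    """Symmetric matrix of pooled two-sample t values on the masked edges."""
    wa = [_as_weights(m) for m in group_a]
    wb = [_as_weights(m) for m in group_b]
    if len(wa) < 2 or len(wb) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    n = wa[0].shape[0]
    iu, ju = np.triu_indices(n, k=1)
    on = mask[iu, ju]
    iu, ju = iu[on], ju[on]
    t = _t_stats(_stack_edges(wa, iu, ju), _stack_edges(wb, iu, ju), tail)
    t_map = np.full((n, n), np.nan)
    t_map[iu, ju] = t
    t_map[ju, iu] = t
    return t_map


def _components_from_edges(edge_list, t_values) -> list[Component]:
    """Breadth-first grouping of edges sharing nodes; sizes are sums of t."""
    adj: dict[int, list[int]] = {}
    for idx, (i, j) in enumerate(edge_list):
        adj.setdefault(i, []).append(idx)
        adj.setdefault(j, []).append(idx)
    seen_edges = set()
    comps = []
    for start_idx in range(len(edge_list)):
        if start_idx in seen_edges:
            continue
        queue = [start_idx]
        seen_edges.add(start_idx)
        edges, nodes = [], set()
        while queue:
            e = queue.pop(0)
            i, j = edge_list[e]
            edges.append((i, j))
            nodes.update((i, j))
            for node in (i, j):
                for nxt in adj[node]:
                    if nxt not in seen_edges:
                        seen_edges.add(nxt)
                        queue.append(nxt)
        comps.append(Component(edges=edges, nodes=nodes,
                               m=float(sum(t_values[e] for e in _indices_of(edges, edge_list)))))
    comps.sort(key=lambda c: -c.m)
    return comps


def _indices_of(edges, edge_list):
    index = {e: k for k, e in enumerate(edge_list)}
    return [index[e] for e in edges]


def suprathreshold_components(t_map: np.ndarray, primary_p: float, df: int,
                              tail: str = "a_less_b") -> tuple[list[Component], float]:
    """Components of edges with t above the one-tailed critical value.

    t* is the upper-tail critical value of Student's t with ``df`` degrees of
    freedom at ``primary_p`` (primary_p/2 per tail for two-sided use);
    membership requires t > t* strictly, and NaN (zero-variance) edges are
    sub-threshold. Returns (components sorted by decreasing M, t*).
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    p = primary_p / 2 if tail == "two_sided" else primary_p
    t_star = float(stats.t.isf(p, df))
    vals = np.abs(t_map) if tail == "two_sided" else t_map
    n = t_map.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore"):
        on = vals[iu, ju] > t_star
    edge_list = list(zip(iu[on].tolist(), ju[on].tolist()))
    t_values = vals[iu, ju][on]
    return _components_from_edges(edge_list, t_values), t_star


def _max_component_size(iu, ju, t_vals, t_star) -> float:
    """Largest sum-of-t component via union-find; 0.0 when nothing is suprathreshold."""
    with np.errstate(invalid="ignore"):
        on = t_vals > t_star
    if not np.any(on):
        return 0.0
    ei, ej, et = iu[on], ju[on], t_vals[on]
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sums: dict[int, float] = {}
    for i, j, t in zip(ei, ej, et):
        i, j = int(i), int(j)
        for node in (i, j):
            if node not in parent:
                parent[node] = node
                sums[node] = 0.0
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
            sums[ri] += sums.pop(rj)
        sums[ri] += float(t)
    return max(sums.values())


def nbs_permutation(group_a, group_b, cfg: AnalysisConfig | None = None,
                    tail: str = "a_less_b", n_perm: int | None = None,
                    mask: np.ndarray | None = None) -> NBSResult:
    """Full NBS: mask, t-map, components, and max-component permutation FWER.

    Group labels are permuted uniformly ``n_perm`` times; each permutation
    recomputes the edgewise t statistics and the largest component intensity
    on the SAME mask and threshold. corrected_p(component) =
    (1 + #{null_max >= M_obs}) / (1 + n_perm), so p is never exactly zero and
    the observed labeling is not double-counted as a permutation.
    """
    cfg = cfg or AnalysisConfig()
    n_perm = cfg.n_perm_nbs if n_perm is None else n_perm
    wa = [_as_weights(m) for m in group_a]
    wb = [_as_weights(m) for m in group_b]
    if len(wa) < 2 or len(wb) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    na, nb = len(wa), len(wb)
    df = na + nb - 2
    if mask is None:
        mask = nbs_mask(wa, wb, cfg.nbs_mask_threshold)
    n = wa[0].shape[0]
    iu_full, ju_full = np.triu_indices(n, k=1)
    on = mask[iu_full, ju_full]
    iu, ju = iu_full[on], ju_full[on]
    X = np.vstack([_stack_edges(wa, iu, ju), _stack_edges(wb, iu, ju)])

    t_obs = _t_stats(X[:na], X[na:], tail)
    t_map = np.full((n, n), np.nan)
    t_map[iu, ju] = t_obs
    t_map[ju, iu] = t_obs
    components, t_star = suprathreshold_components(t_map, cfg.nbs_primary_p, df, tail)

    rng = derive_rng(cfg.seed, "nbs_permutation")
    null_max = np.empty(n_perm)
    use_abs = tail == "two_sided"
    for p_i in range(n_perm):
        perm = rng.permutation(na + nb)
        xa, xb = X[perm[:na]], X[perm[na:]]
        t_p = _t_stats(xa, xb, tail)
        vals = np.abs(t_p) if use_abs else t_p
        null_max[p_i] = _max_component_size(iu, ju, vals, t_star)

    corrected = np.array([
        (1.0 + np.sum(null_max >= c.m)) / (1.0 + n_perm) for c in components
    ])
    return NBSResult(mask=mask, t_map=t_map, primary_t_threshold=t_star,
                     components=components, null_max_sizes=null_max,
                     corrected_p=corrected, alpha=cfg.alpha)
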