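"""Independent brute-force reference implementations for small graphs.

Everything here is pure-python enumeration (loops over nodes, simple paths,
permutations) and deliberately shares no code path with the package.
"""

import itertools
import math


def edges_of(w):
    n = len(w)
    return [(i, j) for i in range(n) for j in range(i + 1, n) if w[i][j] > 0]


def bf_strength(w):
    n = len(w)
    return sum(w[i][j] for i in range(n) for j in range(n)) / n


def bf_density(w):
    n = len(w)
    return len(edges_of(w)) / (n * (n - 1) / 2)


def bf_clustering(w):
    n = len(w)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                j, l = nbrs[a], nbrs[b]
                if w[j][l] > 0:
                    acc += (w[i][j] * w[j][l] * w[l][i]) ** (1.0 / 3.0)
        total += 2.0 / (k * (k - 1)) * acc
    return total / n


def bf_shortest_paths(w):
    """All-pairs shortest 1/w path lengths by enumerating every simple path."""
    n = len(w)
    L = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        L[i][i] = 0.0
    for src in range(n):
        for dst in range(n):
            if src == dst:
                continue
            others = [k for k in range(n) if k not in (src, dst)]
            best = math.inf
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (src,) + mid + (dst,)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if w[a][b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a][b]
                    if ok:
                        best = min(best, length)
            L[src][dst] = best
    return L


def bf_lp(w):
    n = len(w)
    L = bf_shortest_paths(w)
    return sum(L[i][j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))


def bf_eglob(w):
    n = len(w)
    if n < 2:
        return 0.0
    L = bf_shortest_paths(w)
    return sum(
        0.0 if math.isinf(L[i][j]) else 1.0 / L[i][j]
        for i in range(n) for j in range(n) if i != j
    ) / (n * (n - 1))


def bf_eloc(w):
    n = len(w)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        if len(nbrs) < 2:
            continue
        sub = [[w[a][b] for b in nbrs] for a in nbrs]
        total += bf_eglob(sub)
    return total / n


def bf_assortativity(w):
    """Weighted Pearson correlation over the ordered-pair edge expansion."""
    n = len(w)
    strength = [sum(w[i][j] for j in range(n)) for i in range(n)]
    xs, ys, ws = [], [], []
    for (i, j) in edges_of(w):
        for a, b in ((i, j), (j, i)):
            xs.append(strength[a])
            ys.append(strength[b])
            ws.append(w[i][j])
    W = sum(ws)
    mx = sum(wt * x for wt, x in zip(ws, xs)) / W
    my = sum(wt * y for wt, y in zip(ws, ys)) / W
    cov = sum(wt * (x - mx) * (y - my) for wt, x, y in zip(ws, xs, ys)) / W
    vx = sum(wt * (x - mx) ** 2 for wt, x in zip(ws, xs)) / W
    vy = sum(wt * (y - my) ** 2 for wt, y in zip(ws, ys)) / W
    return cov / math.sqrt(vx * vy)


def bf_phi(w, r):
    """Weighted rich-club coefficient by explicit ranking and subset sums."""
    n = len(w)
    k = r * n
    assert abs(k - round(k)) < 1e-9
    k = int(round(k))
    strength = [sum(w[i][j] for j in range(n)) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-strength[i], i))
    club = set(order[:k])
    internal = [w[i][j] for (i, j) in edges_of(w) if i in club and j in club]
    if not internal:
        return None
    all_w = sorted((w[i][j] for (i, j) in edges_of(w)), reverse=True)
    return sum(internal) / sum(all_w[: len(internal)])


def bf_components_sum_t(edge_t):
    """Connected components of an edge->t map; returns sorted sum-of-t sizes."""
    parent = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        return root

    for (i, j) in edge_t:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    sums = {}
    for (i, j), t in edge_t.items():
        r = find(i)
        sums[r] = sums.get(r, 0.0) + t
    return sorted(sums.values(), reverse=True)


def bf_pooled_t(a, b):
    """Textbook pooled two-sample t for B minus A."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (mb - ma) / math.sqrt(sp2 * (1 / na + 1 / nb))


def random_graph(rng, n, p=0.6, connected=False):
    """Random weighted graph as a list-of-lists; optionally resampled until connected."""
    while True:
        w = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    v = 0.1 + 0.9 * rng.random()
                    w[i][j] = w[j][i] = v
        if not connected or _is_connected(w):
            return w


def _is_connected(w):
    n = len(w)
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(n):
            if w[i][j] > 0 and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n
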