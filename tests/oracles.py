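"""Independent brute-force reference implementations used to validate the
package's fast paths. These stay deliberately naive (explicit loops, no
shared code with the package)."""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_naive(a: str, b: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> float:
    """Gotoh affine-gap local alignment score; a gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    neg = -1e18
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            s = _B62[a[i - 1], b[j - 1]]
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def pooled_t_pvalue(x: list[float], y: list[float]) -> float:
    """Closed-form two-sided pooled-variance two-sample t-test."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    t = (mx - my) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    from scipy.stats import t as tdist

    return 2.0 * float(tdist.sf(abs(t), df))


def average_linkage_naive(profiles: dict[str, list[float]]):
    """O(n^3) agglomerative average linkage with Euclidean distance.

    Returns the merge sequence [(frozenset_a, frozenset_b, height)].
    """
    def dist(p, q):
        return math.sqrt(sum((u - v) ** 2 for u, v in zip(p, q)))

    clusters: dict[frozenset, list] = {frozenset([k]): [k] for k in profiles}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters, key=lambda c: sorted(c))
        best = None
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                ca, cb = keys[a], keys[b]
                d = sum(dist(profiles[i], profiles[j])
                        for i in clusters[ca] for j in clusters[cb])
                d /= len(clusters[ca]) * len(clusters[cb])
                if best is None or d < best[0]:
                    best = (d, ca, cb)
        d, ca, cb = best
        merges.append((ca, cb, d))
        clusters[ca | cb] = clusters.pop(ca) + clusters.pop(cb)
    return merges


def bfs_nodes_naive(edges: list[tuple[str, str]], seed: str,
                    radius: int) -> set[str]:
    """Undirected breadth-first neighborhood by explicit frontier walking."""
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    visited = {seed}
    frontier = {seed}
    for _ in range(radius):
        nxt = set()
        for node in frontier:
            nxt |= adj.get(node, set()) - visited
        visited |= nxt
        frontier = nxt
    return visited


def mcl_partition_naive(nodes: list[str],
                        edges: list[tuple[str, str, float]],
                        inflation: float = 1.5, max_iter: int = 100,
                        tol: float = 1e-6) -> list[frozenset[str]]:
    """Pure-python expansion/inflation Markov clustering reference.

    Self-loops equal each node's maximum incident weight (1 when isolated);
    columns are re-normalized after inflation and pruning below tol.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for u, v, w in edges:
        m[idx[u]][idx[v]] = w
        m[idx[v]][idx[u]] = w
    for j in range(n):
        col_max = max(m[i][j] for i in range(n))
        m[j][j] = col_max if col_max > 0 else 1.0

    def normalize(a):
        for j in range(n):
            s = sum(a[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    a[i][j] /= s
        return a

    m = normalize(m)
    for _ in range(max_iter):
        exp = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
               for i in range(n)]
        inf = [[exp[i][j] ** inflation for j in range(n)] for i in range(n)]
        inf = normalize(inf)
        for i in range(n):
            for j in range(n):
                if inf[i][j] < tol:
                    inf[i][j] = 0.0
        inf = normalize(inf)
        delta = max(abs(inf[i][j] - m[i][j])
                    for i in range(n) for j in range(n))
        m = inf
        if delta < tol:
            break

    clusters: list[set[int]] = []
    for i in range(n):
        if m[i][i] > tol:
            members = {j for j in range(n) if m[i][j] > tol} | {i}
            overlapping = [c for c in clusters if c & members]
            for c in overlapping:
                members |= c
                clusters.remove(c)
            clusters.append(members)
    assigned = set()
    for c in clusters:
        assigned |= c
    for j in range(n):
        if j not in assigned:
            col = [m[i][j] for i in range(n)]
            if max(col) > 0:
                target = col.index(max(col))
                placed = False
                for c in clusters:
                    if target in c:
                        c.add(j)
                        placed = True
                        break
                if not placed:
                    clusters.append({j})
            else:
                clusters.append({j})
    return sorted((frozenset(nodes[i] for i in c) for c in clusters),
                  key=lambda s: sorted(s))
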