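"""Independent brute-force reference implementations used only by tests.

Each function re-derives a quantity from its definition with the most
literal (and slowest) algorithm available, deliberately sharing no code
with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def bh_bruteforce(p):
    """Step-up FDR from the definition: adj_i = min_{j: p_j >= p_i} p_j*m/rank_j,
    monotone from the largest p downward."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = min(val, 1.0)
        prev = val
    return adj


def pcoa_eigenvalues_bruteforce(d):
    """Eigenvalues of the hand-centered Gower matrix via a dense solver."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    lam = np.linalg.eigvalsh(b)
    return np.sort(lam)[::-1]


def upgma_merges_bruteforce(labels, d):
    """Literal average-linkage agglomeration tracking all member pairs."""
    d = np.asarray(d, dtype=float)
    idx = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            dd = np.mean([d[idx[x], idx[y]] for x in a for y in b])
            key = (dd, *sorted((min(a), min(b))))
            if best is None or key < best[0]:
                best = (key, a, b, dd)
        _, a, b, dd = best
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(a | b)
        merges.append((set(a), set(b), dd / 2.0))
    return merges


def spearman_bruteforce(x, y):
    """Midrank Spearman as Pearson of hand-computed midranks."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(v.size)
        for i, val in enumerate(v):
            less = np.sum(v < val)
            equal = np.sum(v == val)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else 0.0


def zi_pi_bruteforce(edges, modules):
    """Zi/Pi per node from the definitions, dict-of-sets graph."""
    nodes = sorted(modules)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    within = {
        n: sum(1 for nb in adj[n] if modules[nb] == modules[n]) for n in nodes
    }
    out = {}
    for n in nodes:
        members = [m for m in nodes if modules[m] == modules[n]]
        vals = [within[m] for m in members]
        mu = np.mean(vals)
        sd = np.sqrt(np.mean((np.array(vals) - mu) ** 2))
        zi = (within[n] - mu) / sd if sd > 0 else 0.0
        k = len(adj[n])
        if k == 0:
            pi = 0.0
        else:
            per_mod = {}
            for nb in adj[n]:
                per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        out[n] = (zi, pi)
    return out


def topology_bruteforce(edges, nodes):
    """Nodes/edges/avg degree/centralizations from definitions (no networkx)."""
    nodes = list(nodes)
    n = len(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    m = len(edges)
    deg = {v: len(adj[v]) for v in nodes}
    avg_degree = 2 * m / n if n else 0.0
    if n < 3:
        return dict(n_nodes=n, n_edges=m, avg_degree=avg_degree,
                    degree_centralization=0.0, closeness_centralization=0.0)
    dmax = max(deg.values())
    deg_cent = sum(dmax - deg[v] for v in nodes) / ((n - 1) * (n - 2))

    def bfs(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    clo = {}
    for v in nodes:
        dist = bfs(v)
        comp = len(dist)
        if comp == 1:
            clo[v] = 0.0
        else:
            total = sum(dist.values())
            clo[v] = (comp - 1) / total
    cmax = max(clo.values())
    clo_cent = sum(cmax - clo[v] for v in nodes) / ((n - 1) * (n - 2) / (2 * n - 3))
    return dict(n_nodes=n, n_edges=m, avg_degree=avg_degree,
                degree_centralization=deg_cent,
                closeness_centralization=clo_cent)


def modularity_bruteforce(edges, nodes, partition):
    """Newman–Girvan modularity from the definition."""
    m = len(edges)
    if m == 0:
        return 0.0
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    q = 0.0
    inside = {}
    degsum = {}
    for v in nodes:
        degsum[partition[v]] = degsum.get(partition[v], 0) + deg[v]
    for a, b in edges:
        if partition[a] == partition[b]:
            inside[partition[a]] = inside.get(partition[a], 0) + 1
    for c in degsum:
        q += inside.get(c, 0) / m - (degsum[c] / (2 * m)) ** 2
    return q


def expected_richness_bruteforce(counts, m):
    """E[richness at m draws] by exhaustive enumeration of subsets of reads."""
    reads = []
    for i, c in enumerate(counts):
        reads.extend([i] * c)
    vals = [len(set(comb)) for comb in itertools.combinations(reads, m)]
    return float(np.mean(vals))


def kendall_w_bruteforce(rank_rows):
    """Kendall's W with tie correction, from the textbook formula."""
    ranks = np.asarray(rank_rows, dtype=float)
    m, N = ranks.shape
    r = ranks.sum(axis=0)
    s = ((r - r.mean()) ** 2).sum()
    t = 0.0
    for row in ranks:
        for val in set(row):
            cnt = int(np.sum(row == val))
            t += cnt**3 - cnt
    denom = m**2 * (N**3 - N) - m * t
    return 1.0 if denom <= 0 else 12 * s / denom


def mannwhitney_exact_bruteforce(x, y, alternative="two-sided"):
    """Exact rank-sum p by full enumeration of label arrangements (ties ok)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = x.size

    def ustat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    obs = ustat(range(nx))
    n = pooled.size
    us = [ustat(c) for c in itertools.combinations(range(n), nx)]
    us = np.array(us)
    mean_u = x.size * y.size / 2.0
    if alternative == "two-sided":
        p = np.mean(np.abs(us - mean_u) >= abs(obs - mean_u) - 1e-12)
    elif alternative == "greater":
        p = np.mean(us >= obs - 1e-12)
    else:
        p = np.mean(us <= obs + 1e-12)
    return obs, float(p)
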