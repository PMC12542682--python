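"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with explicit loops and elementary formulas,
deliberately avoiding the code paths (and, where feasible, the
libraries) used by the package itself.
"""

import numpy as np
import scipy.linalg


def levins_breadth_brute(values):
    total = sum(values)
    s = 0.0
    for v in values:
        p = v / total
        s += p * p
    return 1.0 / s


def bray_curtis_brute(x, y):
    num = 0.0
    den = 0.0
    for a, b in zip(x, y):
        num += abs(a - b)
        den += a + b
    return num / den


def beta_mntd_brute(D, fa, fb):
    """Explicit double loop; fa/fb are relative abundances over taxa."""
    term_a = 0.0
    for i in range(len(fa)):
        if fa[i] > 0:
            dmin = min(D[i][j] for j in range(len(fb)) if fb[j] > 0)
            term_a += fa[i] * dmin
    term_b = 0.0
    for j in range(len(fb)):
        if fb[j] > 0:
            dmin = min(D[j][i] for i in range(len(fa)) if fa[i] > 0)
            term_b += fb[j] * dmin
    return 0.5 * (term_a + term_b)


def shortest_paths_floyd_warshall(adj):
    """All-pairs shortest path lengths on an unweighted adjacency matrix."""
    n = len(adj)
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def betweenness_brute(adj):
    """Normalized betweenness by explicit enumeration of shortest paths."""
    n = len(adj)
    d = shortest_paths_floyd_warshall(adj)

    # count shortest paths between every pair by dynamic programming
    npaths = [[0] * n for _ in range(n)]
    for s in range(n):
        order = sorted(range(n), key=lambda v: d[s][v])
        for v in order:
            if v == s:
                npaths[s][v] = 1
                continue
            if d[s][v] == float("inf"):
                continue
            npaths[s][v] = sum(
                npaths[s][u] for u in range(n)
                if adj[u][v] and d[s][u] == d[s][v] - 1
            )
    bc = [0.0] * n
    for s in range(n):
        for t in range(n):
            if s == t or d[s][t] == float("inf"):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s][v] + d[v][t] == d[s][t]:
                    bc[v] += npaths[s][v] * npaths[v][t] / npaths[s][t]
    scale = (n - 1) * (n - 2)  # directed pair count; matches networkx norm
    return [b / scale if scale else 0.0 for b in bc]


def natural_connectivity_brute(adj):
    """NC via the trace of the matrix exponential (independent route)."""
    n = len(adj)
    tr = float(np.trace(scipy.linalg.expm(np.asarray(adj, dtype=float))))
    return float(np.log(tr / n))


def zi_pi_brute(adj, modules):
    """Explicit per-node within/among-module connectivity."""
    n = len(adj)
    out = []
    for i in range(n):
        k = sum(adj[i])
        k_own = sum(adj[i][j] for j in range(n) if modules[j] == modules[i])
        peers = [
            sum(adj[v][j] for j in range(n) if modules[j] == modules[v])
            for v in range(n) if modules[v] == modules[i]
        ]
        mean = sum(peers) / len(peers)
        sd = (sum((p - mean) ** 2 for p in peers) / len(peers)) ** 0.5
        zi = (k_own - mean) / sd if sd > 0 else 0.0
        if k > 0:
            by_mod = {}
            for j in range(n):
                if adj[i][j]:
                    by_mod[modules[j]] = by_mod.get(modules[j], 0) + 1
            pi = 1.0 - sum((v / k) ** 2 for v in by_mod.values())
        else:
            pi = 0.0
        out.append((zi, pi))
    return out


def permanova_pseudo_f_brute(dist, groups):
    """Anderson's pseudo-F from Gower-centered squared distances."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    ident = np.eye(n)
    ones = np.ones((n, n)) / n
    g = (ident - ones) @ a @ (ident - ones)
    ss_total = np.trace(g)
    groups = list(groups)
    ss_within = 0.0
    levels = sorted(set(groups))
    for lev in levels:
        idx = [i for i, grp in enumerate(groups) if grp == lev]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    df_among = len(levels) - 1
    df_within = n - len(levels)
    return (ss_among / df_among) / (ss_within / df_within)
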