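"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration and textbook
formulas, no networkx/statsmodels calls, so the checks are independent of
the code paths under test.  Only feasible for small inputs (n <= 8 graphs,
m <= 50 p-vectors).
"""

from __future__ import annotations

import itertools
import math


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the literal step-up recipe."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, pvalues[i] * m / rank))
        adjusted[i] = running_min
    return adjusted


def floyd_warshall(nodes, edges):
    """All-pairs shortest-path lengths; math.inf for unreachable pairs."""
    dist = {u: {v: math.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0
    for u, v in edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def avg_path_length_brute(nodes, edges):
    dist = floyd_warshall(nodes, edges)
    lengths = [
        dist[u][v]
        for u, v in itertools.combinations(nodes, 2)
        if dist[u][v] < math.inf
    ]
    if not lengths:
        raise ValueError("no reachable pairs")
    return sum(lengths) / len(lengths)


def density_brute(nodes, edges):
    n = len(nodes)
    if n < 2:
        raise ValueError("undefined")
    return len(edges) / (n * (n - 1) / 2)


def transitivity_brute(nodes, edges):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    return 3 * triangles / triples if triples else 0.0


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every shortest s-t path by DFS along the distance gradient."""
    if dist[s][t] == math.inf:
        return []
    paths = []

    def extend(path):
        head = path[-1]
        if head == t:
            paths.append(list(path))
            return
        for nxt in adj[head]:
            if dist[s][nxt] == dist[s][head] + 1 and dist[nxt][t] == dist[s][t] - dist[s][nxt]:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def betweenness_brute(nodes, edges):
    """Unnormalized betweenness via exhaustive shortest-path enumeration."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall(nodes, edges)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def closeness_brute(nodes, edges):
    """1 / (sum of distances to reachable nodes); 0 for isolated nodes."""
    dist = floyd_warshall(nodes, edges)
    out = {}
    for v in nodes:
        total = sum(d for d in dist[v].values() if 0 < d < math.inf)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def spearman_brute(x, y):
    """Spearman rho via Pearson correlation of mid-ranks."""

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
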