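"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, exhaustive search,
textbook formulas) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def all_shortest_paths(adj: dict, weights: dict, src, dst):
    """Enumerate all minimum-weight simple paths src -> dst by DFS."""
    best = [math.inf]
    paths = []

    def dfs(node, cost, path):
        if cost > best[0] + 1e-12:
            return
        if node == dst:
            if cost < best[0] - 1e-12:
                best[0] = cost
                paths.clear()
            paths.append(list(path))
            return
        for nb in adj[node]:
            if nb in path:
                continue
            dfs(nb, cost + weights[frozenset((node, nb))], path + [nb])

    dfs(src, 0.0, [src])
    return best[0], paths


def betweenness_oracle(nodes, edges):
    """Unnormalized weighted betweenness by explicit path enumeration.

    ``edges`` is an iterable of (u, v, w).
    """
    adj = {n: set() for n in nodes}
    weights = {}
    for u, v, w in edges:
        adj[u].add(v)
        adj[v].add(u)
        weights[frozenset((u, v))] = w
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        cost, paths = all_shortest_paths(adj, weights, s, t)
        if not math.isfinite(cost) or not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            through = sum(1 for p in paths if n in p)
            bc[n] += through / len(paths)
    return bc


def dijkstra_oracle(nodes, edges, src):
    """Plain O(V^2) Dijkstra."""
    adj = {n: {} for n in nodes}
    for u, v, w in edges:
        adj[u][v] = min(w, adj[u].get(v, math.inf))
        adj[v][u] = min(w, adj[v].get(u, math.inf))
    dist = {n: math.inf for n in nodes}
    dist[src] = 0.0
    unvisited = set(nodes)
    while unvisited:
        cur = min(unvisited, key=lambda n: dist[n])
        if math.isinf(dist[cur]):
            break
        unvisited.remove(cur)
        for nb, w in adj[cur].items():
            if dist[cur] + w < dist[nb]:
                dist[nb] = dist[cur] + w
    return dist


def closeness_oracle(nodes, edges):
    """1 / sum of weighted distances to reachable others; NaN if isolated."""
    out = {}
    for n in nodes:
        dist = dijkstra_oracle(nodes, edges, n)
        total = sum(d for m, d in dist.items() if m != n and math.isfinite(d))
        out[n] = 1.0 / total if total > 0 else math.nan
    return out


def clustering_oracle(nodes, edges):
    """Unweighted local clustering coefficient; NaN below degree 2."""
    adj = {n: set() for n in nodes}
    for u, v, _ in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for n in nodes:
        nbrs = sorted(adj[n])
        k = len(nbrs)
        if k < 2:
            out[n] = math.nan
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        out[n] = 2.0 * links / (k * (k - 1))
    return out


def cpl_oracle(nodes, edges):
    """Mean unweighted hop count over connected unordered pairs (BFS)."""
    adj = {n: set() for n in nodes}
    for u, v, _ in edges:
        adj[u].add(v)
        adj[v].add(u)
    total, count = 0, 0
    for s, t in itertools.combinations(nodes, 2):
        seen = {s: 0}
        frontier = [s]
        while frontier and t not in seen:
            nxt = []
            for n in frontier:
                for nb in adj[n]:
                    if nb not in seen:
                        seen[nb] = seen[n] + 1
                        nxt.append(nb)
            frontier = nxt
        if t in seen:
            total += seen[t]
            count += 1
    return total / count if count else math.nan


def mst_total_weight_oracle(nodes, edges):
    """Minimum spanning-tree weight by exhaustive enumeration (k <= ~7)."""
    nodes = list(nodes)
    k = len(nodes)
    best = math.inf
    for subset in itertools.combinations(edges, k - 1):
        parent = {n: n for n in nodes}

        def find(n):
            while parent[n] != n:
                parent[n] = parent[parent[n]]
                n = parent[n]
            return n

        acyclic = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic and len({find(n) for n in nodes}) == 1:
            best = min(best, sum(w for _, _, w in subset))
    return best


def spearman_oracle(x, y):
    """Rank correlation via average ranks + the Pearson formula."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def hull_centroid_oracle(points):
    """Convex hull centroid via scipy + the shoelace centroid formula."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return cx, cy


def heterozygosity_oracle(allele_copies):
    """Probability that two gene copies drawn (with replacement) differ,
    by direct enumeration over all ordered pairs."""
    copies = list(allele_copies)
    n = len(copies)
    diff = sum(
        1 for a in copies for b in copies if a != b
    )
    return diff / (n * n)


def random_weighted_graph(rng, k, p=0.5, wmin=0.5, wmax=3.0):
    """(nodes, edges) with random topology and weights."""
    nodes = list(range(k))
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < p:
            edges.append((u, v, float(rng.uniform(wmin, wmax))))
    return nodes, edges
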