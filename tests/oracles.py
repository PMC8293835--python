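"""Independent brute-force oracles for network metrics.

Everything here works by exhaustive enumeration (simple paths, set
partitions, vertex/edge subsets, observation pairs) so it shares no
code path with the package implementation.  Intended for graphs with
at most ~8 nodes.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def enumerate_simple_paths(edge: np.ndarray, s: int, t: int):
    """All simple paths s -> t as node tuples (DFS enumeration)."""
    n = edge.shape[0]
    paths = []

    def walk(node, visited, acc):
        if node == t:
            paths.append(tuple(acc))
            return
        for nxt in range(n):
            if edge[node, nxt] and nxt not in visited:
                walk(nxt, visited | {nxt}, acc + [nxt])

    walk(s, {s}, [s])
    return paths


def shortest_paths(edge: np.ndarray, weights: np.ndarray):
    """dict (s, t) -> (length, list of shortest paths), s < t; brute DFS."""
    n = edge.shape[0]
    out = {}
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(edge, s, t)
            if not paths:
                out[(s, t)] = (np.inf, [])
                continue
            lengths = [sum(weights[a, b] for a, b in zip(p, p[1:]))
                       for p in paths]
            best = min(lengths)
            short = [p for p, ln in zip(paths, lengths)
                     if ln <= best + 1e-9]
            out[(s, t)] = (best, short)
    return out


def betweenness(edge: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pair-counted betweenness: for each unordered pair, the fraction of
    shortest paths through v."""
    n = edge.shape[0]
    sp = shortest_paths(edge, weights)
    btw = np.zeros(n)
    for (s, t), (length, paths) in sp.items():
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return btw


def closeness(edge: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = edge.shape[0]
    sp = shortest_paths(edge, weights)
    close = np.zeros(n)
    for v in range(n):
        total = 0.0
        for u in range(n):
            if u == v:
                continue
            length = sp[(min(u, v), max(u, v))][0]
            if np.isfinite(length):
                total += length
        close[v] = 1.0 / total if total > 0 else 0.0
    return close


def avg_path_length(edge: np.ndarray, weights: np.ndarray) -> float:
    sp = shortest_paths(edge, weights)
    finite = [ln for ln, _ in sp.values() if np.isfinite(ln)]
    return float(np.mean(finite)) if finite else 0.0


def transitivity(edge: np.ndarray) -> float:
    n = edge.shape[0]
    triangles = 0
    triples = 0
    for i, j, k in itertools.combinations(range(n), 3):
        e = int(edge[i, j]) + int(edge[i, k]) + int(edge[j, k])
        if e == 3:
            triangles += 1
            triples += 3  # each triangle contains 3 connected triples
        elif e == 2:
            triples += 1
    return 3.0 * triangles / triples if triples else 0.0


def barrat_coefficient(edge: np.ndarray, sim: np.ndarray) -> float:
    """Mean Barrat local clustering coefficient over nodes of degree >= 2."""
    n = edge.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if edge[i, j]]
        k = len(nbrs)
        s = sum(sim[i, j] for j in nbrs)
        if k < 2 or s == 0:
            continue
        tot = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and edge[j, h]:
                    tot += (sim[i, j] + sim[i, h]) / 2.0
        vals.append(tot / (s * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def modularity(sim: np.ndarray, labels) -> float:
    """Direct double-sum Newman modularity with weights sim."""
    A = np.array(sim, dtype=float)
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    labels = np.asarray(labels)
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def all_partitions(items):
    """Every set partition of items (recursive enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_modularity_partition(sim: np.ndarray):
    n = sim.shape[0]
    best_q, best = -np.inf, None
    for part in all_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            for i in block:
                labels[i] = c
        q = modularity(sim, labels)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def _connected(edge: np.ndarray, nodes) -> bool:
    nodes = list(nodes)
    if len(nodes) <= 1:
        return True
    seen = {nodes[0]}
    stack = [nodes[0]]
    nodeset = set(nodes)
    while stack:
        v = stack.pop()
        for u in nodeset:
            if edge[v, u] and u not in seen:
                seen.add(u)
                stack.append(u)
    return seen == nodeset


def vertex_connectivity(edge: np.ndarray) -> int:
    n = edge.shape[0]
    if n < 2:
        return 0
    if not _connected(edge, range(n)):
        return 0
    if edge[np.triu_indices(n, 1)].all():
        return n - 1  # complete graph convention
    for k in range(0, n - 1):
        for removed in itertools.combinations(range(n), k):
            remaining = [v for v in range(n) if v not in removed]
            if len(remaining) >= 2 and not _connected(edge, remaining):
                return k
    return n - 1


def edge_connectivity(edge: np.ndarray) -> int:
    n = edge.shape[0]
    if n < 2 or not _connected(edge, range(n)):
        return 0
    edges = [(i, j) for i, j in zip(*np.triu_indices(n, 1)) if edge[i, j]]
    for k in range(0, len(edges) + 1):
        for removed in itertools.combinations(edges, k):
            e2 = edge.copy()
            for i, j in removed:
                e2[i, j] = e2[j, i] = False
            if not _connected(e2, range(n)):
                return k
    return len(edges)


def density(edge: np.ndarray) -> float:
    n = edge.shape[0]
    m = edge[np.triu_indices(n, 1)].sum()
    return 2.0 * m / (n * (n - 1)) if n > 1 else 0.0


def adjusted_rand(labelsA, labelsB) -> float:
    """ARI by explicit pair counting over all observation pairs."""
    labelsA, labelsB = np.asarray(labelsA), np.asarray(labelsB)
    n = len(labelsA)
    a = b = c = d = 0  # together/together, together/apart, etc.
    for i, j in itertools.combinations(range(n), 2):
        sa = labelsA[i] == labelsA[j]
        sb = labelsB[i] == labelsB[j]
        if sa and sb:
            a += 1
        elif sa and not sb:
            b += 1
        elif not sa and sb:
            c += 1
        else:
            d += 1
    num = 2.0 * (a * d - b * c)
    den = (a + b) * (b + d) + (a + c) * (c + d)
    return num / den if den else 1.0


def eigenvector_centrality(sim: np.ndarray) -> np.ndarray:
    """Leading eigenvector (by eigendecomposition) of the largest
    connected component, positive sign, zero elsewhere."""
    n = sim.shape[0]
    edge = sim > 0
    # components by flood fill
    comp = -np.ones(n, dtype=int)
    c = 0
    for v in range(n):
        if comp[v] >= 0:
            continue
        stack = [v]
        comp[v] = c
        while stack:
            x = stack.pop()
            for u in range(n):
                if edge[x, u] and comp[u] < 0:
                    comp[u] = c
                    stack.append(u)
        c += 1
    sizes = np.bincount(comp)
    big = int(np.argmax(sizes))
    mask = comp == big
    out = np.zeros(n)
    if mask.sum() >= 2:
        vals, vecs = np.linalg.eigh(sim[np.ix_(mask, mask)])
        v = vecs[:, -1]
        if v.sum() < 0:
            v = -v
        out[mask] = np.abs(v)
    return out
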