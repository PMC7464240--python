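"""Independent brute-force oracles used to validate the native algorithms.

These deliberately avoid the package's own code paths: shortest paths are
enumerated explicitly, eigenvectors come from dense symmetric
eigendecomposition, and modularity cross-checks go through networkx.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from commgenes.graph import Graph


def all_shortest_paths(graph: Graph, s, t) -> list[tuple]:
    """Every shortest s-t path, by BFS predecessor DAG enumeration."""
    dist = {s: 0}
    preds: dict = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    paths = []

    def walk(node, suffix):
        if node == s:
            paths.append((s, *suffix))
            return
        for p in preds[node]:
            walk(p, (node, *suffix))

    walk(t, ())
    return paths


def brute_betweenness_stress(graph: Graph) -> tuple[dict, dict]:
    """Normalized betweenness and raw stress by exhaustive enumeration."""
    from commgenes.network_io import connected_components

    nodes = graph.sorted_nodes()
    betw = {n: 0.0 for n in nodes}
    stress = {n: 0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(graph, s, t)
        if not paths:
            continue
        sigma = len(paths)
        through: dict = {}
        for path in paths:
            for v in path[1:-1]:
                through[v] = through.get(v, 0) + 1
        for v, count in through.items():
            betw[v] += count / sigma
            stress[v] += count
    comp_size = {}
    for comp in connected_components(graph):
        for n in comp:
            comp_size[n] = len(comp)
    for n in nodes:
        size = comp_size[n]
        norm = (size - 1) * (size - 2) / 2
        betw[n] = betw[n] / norm if norm > 0 else 0.0
    return betw, stress


def brute_closeness(graph: Graph) -> dict:
    out = {}
    for s in graph.sorted_nodes():
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        total = sum(dist.values())
        out[s] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def dense_eigenvector(graph: Graph) -> dict:
    """Per-component dominant adjacency eigenvector via numpy.linalg.eigh."""
    from commgenes.network_io import connected_components

    out = {}
    for comp in connected_components(graph):
        comp_nodes = sorted(comp)
        k = len(comp_nodes)
        if k == 1:
            out[comp_nodes[0]] = 1.0
            continue
        idx = {n: i for i, n in enumerate(comp_nodes)}
        mat = np.zeros((k, k))
        for n in comp_nodes:
            for v in graph.neighbors(n):
                mat[idx[n], idx[v]] = 1.0
        _, vecs = np.linalg.eigh(mat)
        vec = vecs[:, -1]
        if vec.sum() < 0:
            vec = -vec
        for n, val in zip(comp_nodes, vec):
            out[n] = float(val)
    return out


def random_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdos-Renyi graph on string node labels (isolated nodes kept)."""
    names = [f"n{i:02d}" for i in range(n)]
    graph = Graph(nodes=names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(names[i], names[j])
    return graph
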