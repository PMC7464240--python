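"""Micro-level centrality metrics: degree, stress, betweenness, closeness,
eigenvector.

Conventions (chosen to match the value ranges these metrics are usually
reported on for PPI hub screens):

* degree — raw incident-edge count (integer);
* stress — raw count of shortest paths through the node, unordered
  source/target pairs counted once (integer, exact arbitrary precision);
* betweenness — Brandes pair-dependency sum normalized by
  ``(n-1)(n-2)/2`` where ``n`` is the node's connected-component size, so
  values lie in [0, 1] (0 when n < 3);
* closeness — within-component: ``(n-1) / sum of distances``; isolated
  nodes get 0;
* eigenvector — dominant eigenvector of the adjacency structure per
  connected component, non-negative, unit Euclidean norm per component,
  computed by power iteration on A + I (the shift makes the iteration
  converge on bipartite components without changing the eigenvectors).

Shortest paths are unweighted (BFS). Path counts are kept as Python
integers so stress is exact even when counts overflow 64 bits.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
from scipy import sparse

from .graph import Graph
from .network_io import connected_components

__all__ = [
    "degree_centrality",
    "betweenness_and_stress",
    "closeness_centrality",
    "eigenvector_centrality",
    "compute_all",
]

METRICS = ("degree", "stress", "betweenness", "closeness", "eigenvector")


def degree_centrality(graph: Graph) -> dict:
    return {n: graph.degree(n) for n in graph.sorted_nodes()}


def _index_adjacency(graph: Graph) -> tuple[list, list[list[int]]]:
    nodes = graph.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [sorted(idx[v] for v in graph.neighbors(n)) for n in nodes]
    return nodes, adj


def _brandes_bfs(adj: list[list[int]], s: int):
    """Single-source BFS returning visit order, path counts, predecessors."""
    n = len(adj)
    sigma = [0] * n
    dist = [-1] * n
    preds: list[list[int]] = [[] for _ in range(n)]
    sigma[s] = 1
    dist[s] = 0
    order: list[int] = []
    queue = deque([s])
    while queue:
        u = queue.popleft()
        order.append(u)
        du = dist[u]
        su = sigma[u]
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = du + 1
                queue.append(v)
            if dist[v] == du + 1:
                sigma[v] += su
                preds[v].append(u)
    return order, sigma, dist, preds


def betweenness_and_stress(graph: Graph) -> dict:
    """Per node: (normalized betweenness, raw stress count).

    Brandes accumulation with a parallel integer counter: for each source
    the number of shortest-path suffixes through a node is accumulated
    alongside the classical pair dependencies, and both totals are halved
    at the end because each unordered pair is seen from both endpoints.
    """
    nodes, adj = _index_adjacency(graph)
    n = len(nodes)
    betw = [0.0] * n
    stress = [0] * n
    for s in range(n):
        order, sigma, _, preds = _brandes_bfs(adj, s)
        delta = [0.0] * n
        phi = [0] * n  # shortest-path suffixes from the node to any target
        for w in reversed(order):
            sw = sigma[w]
            dw = delta[w]
            pw = phi[w]
            for v in preds[w]:
                delta[v] += sigma[v] / sw * (1.0 + dw)
                phi[v] += 1 + pw
            if w != s:
                betw[w] += delta[w]
                stress[w] += sigma[w] * phi[w]

    comp_size = {}
    for comp in connected_components(graph):
        for node in comp:
            comp_size[node] = len(comp)
    out = {}
    for i, node in enumerate(nodes):
        size = comp_size[node]
        norm = (size - 1) * (size - 2) / 2.0
        out[node] = (betw[i] / 2.0 / norm if norm > 0 else 0.0, stress[i] // 2)
    return out


def closeness_centrality(graph: Graph) -> dict:
    """Within-component closeness ``(n_c - 1) / sum of distances``."""
    nodes, adj = _index_adjacency(graph)
    out = {}
    for s, node in enumerate(nodes):
        _, _, dist, _ = _brandes_bfs(adj, s)
        reached = [d for d in dist if d >= 0]
        total = sum(reached)
        out[node] = (len(reached) - 1) / total if total > 0 else 0.0
    return out


def eigenvector_centrality(
    graph: Graph, tol: float = 1e-13, max_iter: int = 100_000
) -> dict:
    """Dominant adjacency eigenvector per component via power iteration.

    Entries are non-negative with unit Euclidean norm within each
    component; singleton components get 1.0. Convergence is declared when
    successive normalized iterates differ by less than ``tol`` in max-norm.
    """
    nodes, adj = _index_adjacency(graph)
    out = {}
    for comp in connected_components(graph):
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            out[comp_nodes[0]] = 1.0
            continue
        local = {n: i for i, n in enumerate(comp_nodes)}
        rows, cols = [], []
        for n in comp_nodes:
            for v in graph.neighbors(n):
                rows.append(local[n])
                cols.append(local[v])
        k = len(comp_nodes)
        adj_mat = sparse.csr_matrix(
            (np.ones(len(rows)), (np.asarray(rows), np.asarray(cols))),
            shape=(k, k),
        )
        x = np.full(k, 1.0 / np.sqrt(k))
        converged = False
        residual = np.inf
        for _ in range(max_iter):
            # y = (A + I) x ; the +I shift guarantees a simple dominant
            # eigenvalue on connected graphs (incl. bipartite ones)
            y = x + adj_mat @ x
            y /= np.linalg.norm(y)
            residual = float(np.max(np.abs(y - x)))
            x = y
            if residual < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"eigenvector power iteration did not converge after "
                f"{max_iter} iterations (residual {residual:.3e}); "
                f"raise max_iter or loosen tol"
            )
        for n, val in zip(comp_nodes, x):
            out[n] = float(abs(val))
    return {n: out[n] for n in nodes}


def compute_all(graph: Graph) -> pd.DataFrame:
    """All five micro-level metrics, one row per node.

    Returns a DataFrame indexed by node with columns ``degree, stress,
    betweenness, closeness, eigenvector``.
    """
    deg = degree_centrality(graph)
    bs = betweenness_and_stress(graph)
    clo = closeness_centrality(graph)
    eig = eigenvector_centrality(graph)
    nodes = graph.sorted_nodes()
    table = pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "stress": [bs[n][1] for n in nodes],
            "betweenness": [bs[n][0] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "eigenvector": [eig[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return table
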