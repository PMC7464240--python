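"""Newman modularity and Louvain-style greedy optimization.

Modularity of a partition of an undirected graph with ``m`` edges is

    Q = sum_c [ e_c / m - gamma * (d_c / (2 m))^2 ]

where ``e_c`` is the number of within-module edges, ``d_c`` the total
degree of module ``c`` and ``gamma`` the resolution parameter (1 by
default). The Louvain heuristic alternates (1) greedy single-node moves to
the neighboring module with the largest positive modularity gain and
(2) aggregation of modules into super-nodes, until Q stops increasing.
Node sweep order is shuffled from an explicit seed; ties among equal-gain
candidate modules go to the lowest module id so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

from .containers import Partition
from .graph import Graph

__all__ = ["modularity_score", "louvain"]

_GAIN_EPS = 1e-12


def modularity_score(graph: Graph, assignment: dict, resolution: float = 1.0) -> float:
    """Modularity Q of ``assignment`` (node -> module id) on ``graph``."""
    m = graph.n_edges
    if m == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    missing = graph.nodes - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} nodes, e.g. {sorted(missing)[:5]}")
    e_c: dict = {}
    d_c: dict = {}
    for node in graph.nodes:
        c = assignment[node]
        d_c[c] = d_c.get(c, 0) + graph.degree(node)
    for u, v in graph.edges():
        if assignment[u] == assignment[v]:
            c = assignment[u]
            e_c[c] = e_c.get(c, 0) + 1
    two_m = 2.0 * m
    return sum(
        e_c.get(c, 0) / m - resolution * (d / two_m) ** 2 for c, d in d_c.items()
    )


def _one_level(adj, loops, k, m, resolution, rng, move_log=None, node_names=None):
    """One Louvain local-move phase on a weighted graph.

    ``adj`` is a list of dicts (off-diagonal weights), ``loops`` self-loop
    weights, ``k`` weighted degrees (incl. 2*loop), ``m`` total edge
    weight. Returns (community array, moved_any). When ``move_log`` is a
    list, each accepted move appends ``(assignment_before, node, new_comm,
    delta_q)`` with original node names (only meaningful at level 0).
    """
    n = len(adj)
    comm = list(range(n))
    tot = k.copy()  # total weighted degree per community
    two_m = 2.0 * m
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            ki = k[i]
            # weights from i to each neighboring community (self excluded)
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            tot[ci] -= ki
            base = links.get(ci, 0.0) / m - resolution * tot[ci] * ki / (2.0 * m * m)
            best_c, best_gain = ci, 0.0
            for c in sorted(links):
                if c == ci:
                    continue
                gain = links[c] / m - resolution * tot[c] * ki / (2.0 * m * m) - base
                if gain > best_gain + _GAIN_EPS or (
                    abs(gain - best_gain) <= _GAIN_EPS and best_gain > 0 and c < best_c
                ):
                    best_c, best_gain = c, gain
            if best_c != ci:
                if move_log is not None:
                    before = {node_names[t]: comm[t] for t in range(n)}
                    move_log.append((before, node_names[i], best_c, best_gain))
                comm[i] = best_c
                improved = True
                moved_any = True
            tot[comm[i]] += ki
    return comm, moved_any


def _aggregate(adj, loops, comm):
    """Collapse communities into super-nodes, summing weights."""
    labels = sorted(set(comm))
    remap = {c: i for i, c in enumerate(labels)}
    n_new = len(labels)
    new_adj: list[dict[int, float]] = [{} for _ in range(n_new)]
    new_loops = [0.0] * n_new
    for i, nbrs in enumerate(adj):
        ci = remap[comm[i]]
        new_loops[ci] += loops[i]
        for j, w in nbrs.items():
            cj = remap[comm[j]]
            if ci == cj:
                if i < j:
                    new_loops[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    return new_adj, new_loops, remap


def louvain(
    graph: Graph,
    resolution: float = 1.0,
    seed: int = 0,
    move_log: list | None = None,
) -> Partition:
    """Louvain community detection.

    Parameters
    ----------
    graph
        Graph with at least one edge.
    resolution
        Resolution parameter gamma of the modularity quality function.
    seed
        Seed for the node sweep order.
    move_log
        Optional list; when given, level-0 accepted moves are recorded as
        ``(assignment_before, node, new_module, delta_q)`` for auditing.

    Returns
    -------
    Partition with contiguous module ids (ordered by first appearance over
    the sorted node list), the final modularity ``q`` and per-level
    modularity values ``level_qs``.
    """
    if graph.n_edges == 0:
        raise ValueError("Louvain requires a graph with at least one edge")
    rng = np.random.default_rng(seed)
    nodes = graph.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    adj: list[dict[int, float]] = [
        {idx[v]: 1.0 for v in graph.neighbors(n)} for n in nodes
    ]
    loops = [0.0] * len(nodes)
    m = float(graph.n_edges)

    # membership of each original node in the current coarse graph
    node_of = list(range(len(nodes)))
    assignment = {n: i for i, n in enumerate(nodes)}
    prev_assignment = assignment
    level_qs: list[float] = []
    prev_q = modularity_score(graph, assignment, resolution)

    level = 0
    while True:
        k = [sum(nbrs.values()) + 2.0 * loops[i] for i, nbrs in enumerate(adj)]
        comm, moved = _one_level(
            adj,
            loops,
            k,
            m,
            resolution,
            rng,
            move_log=move_log if level == 0 else None,
            node_names=nodes if level == 0 else None,
        )
        assignment = {n: comm[node_of[i]] for i, n in enumerate(nodes)}
        q = modularity_score(graph, assignment, resolution)
        level_qs.append(q)
        if not moved or q <= prev_q + _GAIN_EPS:
            if q < prev_q:  # never return a worse partition than the last level
                assignment = prev_assignment
                q = prev_q
            break
        prev_q = q
        prev_assignment = assignment
        adj, loops, remap = _aggregate(adj, loops, comm)
        node_of = [remap[comm[node_of[i]]] for i in range(len(nodes))]
        level += 1

    # relabel modules contiguously by first appearance in sorted node order
    relabel: dict = {}
    for n in nodes:
        c = assignment[n]
        if c not in relabel:
            relabel[c] = len(relabel)
    assignment = {n: relabel[assignment[n]] for n in nodes}
    return Partition(assignment=assignment, q=q, level_qs=level_qs)
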