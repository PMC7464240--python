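"""Undirected, unweighted simple graph over gene-symbol identifiers."""

from __future__ import annotations

from collections.abc import Hashable, Iterable


class Graph:
    """A simple undirected graph.

    Nodes are hashable, sortable identifiers (gene symbols throughout this
    package). Self-loops and parallel edges are rejected so degree and
    shortest-path counts keep their combinatorial meaning. Iteration orders
    are made deterministic by sorting wherever order can leak into results.
    """

    __slots__ = ("_adj",)

    def __init__(
        self,
        edges: Iterable[tuple[Hashable, Hashable]] = (),
        nodes: Iterable[Hashable] = (),
    ) -> None:
        self._adj: dict[Hashable, set] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    def add_node(self, node: Hashable) -> None:
        self._adj.setdefault(node, set())

    def add_edge(self, u: Hashable, v: Hashable) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> frozenset:
        return frozenset(self._adj)

    def sorted_nodes(self) -> list:
        return sorted(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def edges(self) -> set[tuple]:
        """Edge set as sorted 2-tuples (one tuple per undirected edge)."""
        out = set()
        for u, nbrs in self._adj.items():
            for v in nbrs:
                out.add((u, v) if u <= v else (v, u))
        return out

    def neighbors(self, node: Hashable) -> frozenset:
        return frozenset(self._adj[node])

    def degree(self, node: Hashable) -> int:
        return len(self._adj[node])

    def has_node(self, node: Hashable) -> bool:
        return node in self._adj

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        return u in self._adj and v in self._adj[u]

    # -- derived graphs --------------------------------------------------
    def subgraph(self, keep: Iterable[Hashable]) -> "Graph":
        """Induced subgraph on ``keep`` ∩ nodes (absent names ignored)."""
        keep = set(keep) & set(self._adj)
        sub = Graph(nodes=keep)
        for u in keep:
            for v in self._adj[u]:
                if v in keep and u < v:
                    sub.add_edge(u, v)
        return sub

    def copy(self) -> "Graph":
        g = Graph()
        g._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        return g

    # -- dunder ----------------------------------------------------------
    def __contains__(self, node: Hashable) -> bool:
        return node in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
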