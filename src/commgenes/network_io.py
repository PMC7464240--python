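"""STRING-dialect edge lists, induced subgraphs and component summaries.

The edge-list dialect is a tab-separated file with a header naming two
identifier columns (``node1``/``node2``, aliases ``protein1``/``protein2``)
and a confidence column ``combined_score`` (alias ``score``). STRING
serializes combined scores either as fractions in [0, 1] or as integers on
a 0-1000 scale; the scale is auto-detected (any score > 1 implies the
0-1000 dialect) and thresholding is applied on the [0, 1] scale with an
inclusive minimum.
"""

from __future__ import annotations

import logging
from collections import deque
from pathlib import Path
from xml.sax.saxutils import quoteattr

import pandas as pd

from .containers import ComponentSummary
from .graph import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "read_string_edges",
    "write_edges",
    "write_graphml",
    "induced_subgraph",
    "connected_components",
    "summarize_components",
]

_NODE1_ALIASES = ("node1", "protein1")
_NODE2_ALIASES = ("node2", "protein2")
_SCORE_ALIASES = ("combined_score", "score")


def _pick_column(columns, aliases, path):
    for name in aliases:
        if name in columns:
            return name
    raise ValueError(
        f"{path}: missing required column; expected one of {aliases}, "
        f"found {list(columns)}"
    )


def read_string_edges(path, min_combined_score: float = 0.4) -> Graph:
    """Read a STRING-dialect TSV into a simple undirected graph.

    Rows with score >= ``min_combined_score`` (after scale detection) are
    retained; self-pairs are dropped and duplicate/reversed pairs collapse
    to one undirected edge. Nodes are the endpoints of retained edges.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    c1 = _pick_column(df.columns, _NODE1_ALIASES, path)
    c2 = _pick_column(df.columns, _NODE2_ALIASES, path)
    cs = _pick_column(df.columns, _SCORE_ALIASES, path)

    score = pd.to_numeric(df[cs], errors="coerce")
    bad = score.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: unparseable score {df[cs][bad.idxmax()]!r} at line {line}")
    if (score > 1).any():
        score = score / 1000.0  # 0-1000 integer dialect

    keep = score >= min_combined_score
    graph = Graph()
    n_self = 0
    for u, v in zip(df[c1][keep], df[c2][keep]):
        if u == v:
            n_self += 1
            continue
        graph.add_edge(u, v)
    if n_self:
        logger.info("dropped %d self-pairs from %s", n_self, path)
    return graph


def write_edges(graph: Graph, path, score: float = 1.0) -> None:
    """Write the graph as a STRING-dialect TSV (constant score)."""
    int_score = int(round(score * 1000))
    rows = sorted(graph.edges())
    frame = pd.DataFrame(rows, columns=["node1", "node2"])
    frame["combined_score"] = int_score
    frame.to_csv(path, sep="\t", index=False)


def write_graphml(graph: Graph, path) -> None:
    """Write the graph as minimal undirected GraphML."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <graph edgedefault="undirected">',
    ]
    for node in graph.sorted_nodes():
        lines.append(f"    <node id={quoteattr(str(node))} />")
    for u, v in sorted(graph.edges()):
        lines.append(
            f"    <edge source={quoteattr(str(u))} target={quoteattr(str(v))} />"
        )
    lines += ["  </graph>", "</graphml>", ""]
    Path(path).write_text("\n".join(lines))


def induced_subgraph(graph: Graph, genes) -> Graph:
    """Subgraph on ``genes`` ∩ nodes; absent genes are ignored with a log."""
    genes = set(genes)
    absent = genes - graph.nodes
    if absent:
        logger.warning(
            "%d of %d requested genes absent from graph", len(absent), len(genes)
        )
    return graph.subgraph(genes)


def connected_components(graph: Graph) -> list[set]:
    """Connected components, largest first (ties by smallest member)."""
    seen: set = set()
    comps: list[set] = []
    for start in graph.sorted_nodes():
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def summarize_components(graph: Graph) -> ComponentSummary:
    comps = connected_components(graph)
    histogram: dict[int, int] = {}
    for comp in comps:
        histogram[len(comp)] = histogram.get(len(comp), 0) + 1
    return ComponentSummary(
        n_components=len(comps),
        size_histogram=dict(sorted(histogram.items())),
        largest_size=len(comps[0]) if comps else 0,
        total_connected_nodes=sum(len(c) for c in comps if len(c) >= 2),
        n_singletons=histogram.get(1, 0),
    )
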