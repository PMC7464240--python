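"""Top-gene subnetworks and gene-set over-representation analysis.

Over-representation uses the upper-tail hypergeometric test: drawing the
study set from the background, the p-value for a gene set with ``K``
background members is ``P(overlap >= k)``. The background defaults (at the
pipeline level) to the genes of the analyzed network rather than the whole
genome, since the tested sets are drawn from network nodes. BH adjustment
reuses :func:`commgenes.dge.bh_adjust` so the two modules agree bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .graph import Graph
from .network_io import induced_subgraph

__all__ = [
    "intra_module_subnet",
    "inter_module_subnet",
    "InterModuleSubnet",
    "ora_hypergeometric",
    "read_gmt",
]


def intra_module_subnet(graph152: Graph, top_genes, module_members) -> Graph:
    """Induced subgraph of the re-induced network on one module's top genes."""
    top_genes = set(top_genes)
    stray = top_genes - set(module_members)
    if stray:
        raise ValueError(
            f"top genes outside the module: {sorted(stray)}"
        )
    return induced_subgraph(graph152, top_genes)


@dataclass
class InterModuleSubnet:
    """Induced subgraph over two modules' top genes with edge classes."""

    graph: Graph
    edge_classes: dict[tuple, str]  # sorted edge tuple -> within-1/within-2/between

    def class_counts(self) -> dict[str, int]:
        counts = {"within-1": 0, "within-2": 0, "between": 0}
        for label in self.edge_classes.values():
            counts[label] += 1
        return counts


def inter_module_subnet(graph152: Graph, top1, top2) -> InterModuleSubnet:
    """Subgraph on the union of two disjoint top-gene sets, edges labeled
    ``within-1``, ``within-2`` or ``between`` by endpoint membership."""
    top1, top2 = set(top1), set(top2)
    overlap = top1 & top2
    if overlap:
        raise ValueError(f"top-gene sets overlap: {sorted(overlap)}")
    sub = induced_subgraph(graph152, top1 | top2)
    classes = {}
    for u, v in sub.edges():
        if u in top1 and v in top1:
            classes[(u, v)] = "within-1"
        elif u in top2 and v in top2:
            classes[(u, v)] = "within-2"
        else:
            classes[(u, v)] = "between"
    return InterModuleSubnet(graph=sub, edge_classes=classes)


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: set name, description, tab-separated gene symbols."""
    collection: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:80]!r}")
        collection[fields[0]] = {g for g in fields[2:] if g}
    return collection


def ora_hypergeometric(study, collection: dict[str, set], background) -> pd.DataFrame:
    """Hypergeometric over-representation of ``study`` in each gene set.

    Each set is intersected with the background before testing. Rows are
    sorted by ascending p then set name; ``fdr`` is BH across the tested
    sets.
    """
    study = set(study)
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    stray = study - background
    if stray:
        raise ValueError(f"study genes outside background: {sorted(stray)[:10]}")
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & background
        overlap = len(members & study)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=len(members), n=n_study)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_study))
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": len(members),
                "study_size": n_study,
                "background_size": n_bg,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "set_name"], kind="mergesort").reset_index(
            drop=True
        )
    return result
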