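"""Published reference values for the psoriasis PPI case study.

The workflow this package implements was originally applied to paired
lesional/non-lesional psoriasis biopsies (GEO accession GSE30999, STRING
v10.5 edges). The full inputs are not redistributable at desk scale, but
the published summary values — threshold settings, the per-module ranked
centrality tables of the top communicative genes, and the component
profile of the DEG network — are small enough to ship and serve as worked
examples and regression anchors for the selection logic.
"""

from __future__ import annotations

import pandas as pd

from .containers import ThresholdSpec
from .graph import Graph

__all__ = [
    "DEG_CUTOFFS",
    "PRIMARY_THRESHOLDS",
    "MODULE1_THRESHOLDS",
    "MODULE2_THRESHOLDS",
    "MODULE1_TOP_GENES",
    "MODULE2_TOP_GENES",
    "COMPONENT_PROFILE",
    "module1_centrality_fixture",
    "build_component_profile_graph",
]

# DEG stage cutoffs of the case study
DEG_CUTOFFS = {"p_max": 0.01, "fdr_max": 0.01, "min_abs_logfc": 1.0, "top_n": 2000}

# micro-level thresholds on the full DEG network (union -> primary genes)
PRIMARY_THRESHOLDS = ThresholdSpec(
    min_values={"degree": 50, "stress": 200_000, "eigenvector": 0.05}
)

# per-module thresholds on the re-induced primary-gene network
MODULE1_THRESHOLDS = ThresholdSpec(
    min_values={"degree": 87, "stress": 8732, "betweenness": 0.03}
)
MODULE2_THRESHOLDS = ThresholdSpec(
    min_values={"degree": 26, "eigenvector": 0.007, "stress": 8518, "betweenness": 0.04}
)

# top communicative genes reported for the two modules (cell cycle / immune)
MODULE1_TOP_GENES = frozenset(
    {"CCNA2", "CCNB1", "CDC20", "CDK1", "FOXM1", "MKI67"}
)
MODULE2_TOP_GENES = frozenset(
    {
        "STAT3", "EGF", "H2AFX", "IL1B", "IFNG", "STAT1",
        "CXCL8", "CXCL10", "MAPK14", "MCL1", "UBE2N",
    }
)

# connected-component profile of the published DEG network:
# one 1445-gene component, two 3-gene components, fifteen 2-gene components
COMPONENT_PROFILE = {1445: 1, 3: 2, 2: 15}

# published module-1 ranked values: (degree, betweenness, stress); None
# marks cells the ranked tables do not list (value below the cut)
_MODULE1_PUBLISHED = {
    "CCNB1": (92, 0.05, 15_636),
    "CDC20": (91, 0.04, 8_732),
    "CDK1": (90, None, 10_020),
    "CCNA2": (87, None, 9_618),
    "MKI67": (None, 0.04, 13_412),
    "FOXM1": (None, 0.03, 8_920),
}

# synthetic stand-ins for the unlisted cells: any value strictly below the
# module-1 thresholds reproduces the published selection
_BELOW = {"degree": 60, "betweenness": 0.01, "stress": 5_000}


def module1_centrality_fixture() -> pd.DataFrame:
    """Centrality table carrying the published module-1 ranked values.

    Cells absent from the ranked tables are filled with synthetic
    below-threshold placeholders; closeness and eigenvector (not used by
    the module-1 thresholds) carry nominal constants. Applying
    :data:`MODULE1_THRESHOLDS` to this table reproduces the published
    six-gene top set.
    """
    rows = {}
    for gene, (deg, btw, stress) in _MODULE1_PUBLISHED.items():
        rows[gene] = {
            "degree": deg if deg is not None else _BELOW["degree"],
            "stress": stress if stress is not None else _BELOW["stress"],
            "betweenness": btw if btw is not None else _BELOW["betweenness"],
            "closeness": 0.5,
            "eigenvector": 0.1,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "node"
    return table


def build_component_profile_graph(profile: dict[int, int] | None = None) -> Graph:
    """Construct a graph matching a component-size profile.

    Each component of size s is wired as a path (sufficient for component
    counting; topology within components is not part of the profile).
    """
    profile = dict(COMPONENT_PROFILE) if profile is None else dict(profile)
    graph = Graph()
    comp_id = 0
    for size in sorted(profile, reverse=True):
        for _ in range(profile[size]):
            comp_id += 1
            chain = [f"C{comp_id:04d}_{i + 1:04d}" for i in range(size)]
            if size == 1:
                graph.add_node(chain[0])
            for a, b in zip(chain, chain[1:]):
                graph.add_edge(a, b)
    return graph
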