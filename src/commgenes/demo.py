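"""A planted "super-hub" demonstration dataset for the full pipeline.

Construction: two modules whose designated super-hubs are wired to every
member of their module (so they dominate degree, stress, betweenness and
eigenvector within the module by a wide margin), non-hub members connected
sparsely among themselves, and a single bridge edge joining the modules.
All module genes carry strong true fold changes so the DEG filter passes
them; a few decoy genes with no effect sit in the edge file to exercise
the DEG restriction, and some pure-noise genes sit in the expression
matrix only. Running the pipeline on this dataset with the shipped
thresholds recovers the planted super-hub sets exactly as the per-module
top communicative genes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import RunConfig
from .synthetic import generate_expression

__all__ = ["build_superhub_demo"]

_N_MODULE_A, _N_HUBS_A = 40, 6
_N_MODULE_B, _N_HUBS_B = 45, 11
_P_PEER = 0.15  # edge probability among non-hub module members
_N_DECOYS = 5  # non-differential genes present in the edge file
_N_NOISE = 10  # non-differential genes absent from the edge file


def build_superhub_demo(out_dir, seed: int = 0) -> tuple[RunConfig, dict[str, set]]:
    """Write the demo dataset and return (run config, planted truth).

    The truth maps ``"module_a"``/``"module_b"`` to the planted super-hub
    gene sets the pipeline should report as top communicative genes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    mod_a = [f"MA{i + 1:02d}" for i in range(_N_MODULE_A)]
    mod_b = [f"MB{i + 1:02d}" for i in range(_N_MODULE_B)]
    hubs_a, hubs_b = set(mod_a[:_N_HUBS_A]), set(mod_b[:_N_HUBS_B])
    decoys = [f"DX{i + 1:02d}" for i in range(_N_DECOYS)]
    noise = [f"NZ{i + 1:02d}" for i in range(_N_NOISE)]

    edges: set[tuple[str, str]] = set()

    def add(u: str, v: str) -> None:
        edges.add((u, v) if u < v else (v, u))

    for members, hubs in ((mod_a, hubs_a), (mod_b, hubs_b)):
        for hub in sorted(hubs):
            for other in members:
                if other != hub:
                    add(hub, other)
        non_hubs = [g for g in members if g not in hubs]
        for i, u in enumerate(non_hubs):
            for v in non_hubs[i + 1 :]:
                if rng.random() < _P_PEER:
                    add(u, v)
    add(sorted(hubs_a)[0], sorted(hubs_b)[0])  # single inter-module bridge
    for decoy in decoys:  # decoys hang off random non-hub members
        add(decoy, str(rng.choice([g for g in mod_a + mod_b])))

    genes = sorted(mod_a + mod_b + decoys + noise)
    expr, _ = generate_expression(
        n_genes=len(genes),
        n_pairs=30,
        effect_range=(1.5, 2.5),
        noise_sd=0.3,
        probes_per_gene=(1, 2),
        seed=int(rng.integers(2**31 - 1)),
        gene_names=genes,
        de_genes=sorted(mod_a + mod_b),
    )

    expr.values.to_csv(out_dir / "expression.tsv", sep="\t", index_label="probe")
    pd.DataFrame(
        {
            "sample": expr.design.index,
            "patient_condition": expr.design["patient"] + ":" + expr.design["condition"],
        }
    ).to_csv(out_dir / "design.tsv", sep="\t", index=False)
    expr.probe_map.rename("gene").to_csv(
        out_dir / "probe_map.tsv", sep="\t", index_label="probe"
    )
    edge_rows = sorted(edges)
    pd.DataFrame(
        {
            "node1": [u for u, _ in edge_rows],
            "node2": [v for _, v in edge_rows],
            "combined_score": 900,
        }
    ).to_csv(out_dir / "edges.tsv", sep="\t", index=False)

    hub_degree_cut = 30  # hubs have degree >= 39; non-hubs stay far below
    config = RunConfig(
        expression=str(out_dir / "expression.tsv"),
        design=str(out_dir / "design.tsv"),
        probe_map=str(out_dir / "probe_map.tsv"),
        edges=str(out_dir / "edges.tsv"),
        primary_thresholds={"degree": 1},  # carry the whole main component forward
        module_thresholds={m: {"degree": hub_degree_cut} for m in range(4)},
        seed=seed,
        outdir=str(out_dir / "run"),
    )
    return config, {"module_a": hubs_a, "module_b": hubs_b}
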