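"""Synthetic paired expression matrices and planted PPI graphs.

The generators emulate the statistical structure the pipeline assumes so
every downstream stage is testable without external downloads:

* :func:`generate_expression` — a paired non-lesional/lesional (NL/LL)
  log2 expression matrix. Gene baselines are normal on the log2 scale
  (location ~8, sd ~2, mimicking normalized microarray intensities), each
  gene carries 1..k probes with small probe-specific offsets (so
  probe-to-gene collapse is nontrivial), patients carry a shared random
  shift (removed by pairing), and a chosen fraction of genes receives a
  true log2 fold change in the LL condition.
* :func:`generate_ppi` — an undirected simple graph with two planted dense
  modules (within-module edge probability ``p_in``), sparse background
  (``p_out``), hub nodes with extra random attachments, and small
  disconnected 2-3-node components wired as paths.
* :func:`write_fixture_bundle` — a coherent on-disk bundle (expression,
  design, probe map, STRING-dialect edges, truth) in which the planted
  graph's genes are the differential genes, mirroring a workflow where
  DEGs are submitted to a PPI database.

All randomness flows through one explicit integer seed; no global state.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SyntheticTruth
from .graph import Graph

__all__ = [
    "generate_expression",
    "generate_ppi",
    "write_fixture_bundle",
    "read_expression",
    "read_truth",
]


def _check_positive(name: str, value) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")


def generate_expression(
    n_genes: int,
    n_pairs: int,
    de_fraction: float = 0.2,
    effect_range: tuple[float, float] = (1.0, 3.0),
    noise_sd: float = 0.5,
    probes_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    probe_offset_sd: float = 0.25,
    patient_sd: float = 0.5,
    gene_names=None,
    de_genes=None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a paired NL/LL log2 expression matrix with ground truth.

    Parameters
    ----------
    n_genes, n_pairs
        Number of genes and of NL/LL patient pairs (>= 2).
    de_fraction
        Fraction of genes given a nonzero true log2 fold change (ignored
        when ``de_genes`` is supplied).
    effect_range
        Interval of |log2FC| magnitudes; signs are random.
    noise_sd
        Per-sample residual noise sd on the log2 scale.
    probes_per_gene
        (lo, hi): per-gene probe counts drawn uniformly; at least one gene
        is guaranteed >= 2 probes whenever hi >= 2.
    gene_names, de_genes
        Optional overrides for gene symbols and the differential set (used
        by :func:`write_fixture_bundle` to keep expression and graph
        coherent).
    """
    _check_positive("n_genes", n_genes)
    _check_positive("n_pairs", n_pairs)
    if n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {n_pairs}")
    if not 0 <= de_fraction <= 1:
        raise ValueError(f"de_fraction must lie in [0, 1], got {de_fraction}")
    _check_positive("noise_sd", noise_sd)

    rng = np.random.default_rng(seed)
    genes = list(gene_names) if gene_names is not None else [
        f"G{i + 1:05d}" for i in range(n_genes)
    ]
    if len(genes) != n_genes:
        raise ValueError("gene_names length does not match n_genes")

    lo, hi = probes_per_gene
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid probes_per_gene interval {probes_per_gene}")
    probe_counts = rng.integers(lo, hi + 1, size=n_genes)
    if hi >= 2 and not (probe_counts >= 2).any():
        probe_counts[0] = 2
    probes = []
    probe_gene = []
    for g, count in zip(genes, probe_counts):
        for j in range(count):
            probes.append(f"{g}_p{j + 1}")
            probe_gene.append(g)
    probe_map = pd.Series(probe_gene, index=pd.Index(probes, name="probe"), name="gene")

    if de_genes is not None:
        de_genes = sorted(set(de_genes))
        unknown = set(de_genes) - set(genes)
        if unknown:
            raise ValueError(f"de_genes not among generated genes: {sorted(unknown)[:5]}")
    else:
        n_de = int(round(de_fraction * n_genes))
        de_genes = sorted(rng.choice(genes, size=n_de, replace=False))
    magnitudes = rng.uniform(effect_range[0], effect_range[1], size=len(de_genes))
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    effect_sizes = {g: 0.0 for g in genes}
    for g, mag, sign in zip(de_genes, magnitudes, signs):
        effect_sizes[g] = float(sign * mag)

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    baseline_of = dict(zip(genes, baseline))
    offsets = rng.normal(0.0, probe_offset_sd, size=len(probes))
    patient_shift = rng.normal(0.0, patient_sd, size=n_pairs)

    patients = [f"P{i + 1:03d}" for i in range(n_pairs)]
    samples = []
    design_rows = []
    for pat in patients:
        for cond in ("NL", "LL"):
            samples.append(f"{pat}_{cond}")
            design_rows.append({"patient": pat, "condition": cond})
    design = pd.DataFrame(design_rows, index=pd.Index(samples, name="sample"))

    probe_base = np.array([baseline_of[g] for g in probe_gene]) + offsets
    probe_effect = np.array([effect_sizes[g] for g in probe_gene])
    values = np.empty((len(probes), len(samples)))
    for s_idx, sample in enumerate(samples):
        pat_idx = s_idx // 2
        is_ll = s_idx % 2 == 1
        col = probe_base + patient_shift[pat_idx]
        if is_ll:
            col = col + probe_effect
        values[:, s_idx] = col
    values += rng.normal(0.0, noise_sd, size=values.shape)

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_map.index, columns=samples),
        design=design,
        probe_map=probe_map,
    )
    truth = SyntheticTruth(
        de_genes=set(de_genes),
        effect_sizes=effect_sizes,
        module_assignment={g: "background" for g in genes},
        hub_genes=set(),
    )
    return expr, truth


def generate_ppi(
    module_sizes: tuple[int, int] = (86, 63),
    n_background: int = 200,
    p_in: float = 0.3,
    p_out: float = 0.01,
    n_hubs: int = 5,
    hub_extra_degree: int = 30,
    n_small_components: int = 4,
    seed: int = 0,
    gene_names=None,
) -> tuple[Graph, SyntheticTruth]:
    """Generate a planted-module PPI graph with hubs and small components.

    Two dense blocks of sizes ``module_sizes`` get within-block edge
    probability ``p_in``; every other main-block pair (cross-module or
    background) gets ``p_out``. ``n_hubs`` nodes sampled from the main
    block receive ``hub_extra_degree`` additional random attachments.
    ``n_small_components`` disconnected path components of 2-3 nodes are
    appended. The graph is simple.
    """
    s1, s2 = module_sizes
    if s1 < 3 or s2 < 3:
        raise ValueError(f"module sizes must be >= 3, got {module_sizes}")
    if not p_in > p_out:
        raise ValueError(
            f"p_in ({p_in}) must exceed p_out ({p_out}); "
            "planted structure is unidentifiable otherwise"
        )
    for name, value in (("n_background", n_background),
                        ("n_hubs", n_hubs),
                        ("hub_extra_degree", hub_extra_degree),
                        ("n_small_components", n_small_components)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")

    rng = np.random.default_rng(seed)
    n_main = s1 + s2 + n_background
    small_sizes = rng.choice([2, 3], size=n_small_components, p=[0.85, 0.15])
    n_total = n_main + int(small_sizes.sum())
    names = list(gene_names) if gene_names is not None else [
        f"G{i + 1:05d}" for i in range(n_total)
    ]
    if len(names) < n_total:
        raise ValueError(f"need {n_total} gene names, got {len(names)}")
    names = names[:n_total]

    membership = np.zeros(n_main, dtype=int)  # 0=module1, 1=module2, 2=background
    membership[s1 : s1 + s2] = 1
    membership[s1 + s2 :] = 2

    graph = Graph(nodes=names)
    iu, ju = np.triu_indices(n_main, k=1)
    same_module = (membership[iu] == membership[ju]) & (membership[iu] < 2)
    probs = np.where(same_module, p_in, p_out)
    drawn = rng.random(iu.size) < probs
    for i, j in zip(iu[drawn], ju[drawn]):
        graph.add_edge(names[i], names[j])

    hubs: set = set()
    if n_hubs > 0:
        hub_idx = sorted(rng.choice(n_main, size=n_hubs, replace=False))
        for h in hub_idx:
            hub = names[h]
            hubs.add(hub)
            candidates = [
                names[i]
                for i in range(n_main)
                if i != h and not graph.has_edge(hub, names[i])
            ]
            extra = min(hub_extra_degree, len(candidates))
            for other in rng.choice(candidates, size=extra, replace=False):
                graph.add_edge(hub, other)

    pos = n_main
    for size in small_sizes:
        chain = names[pos : pos + size]
        for a, b in zip(chain, chain[1:]):
            graph.add_edge(a, b)
        pos += size

    assignment = {}
    for i, name in enumerate(names):
        if i < s1:
            assignment[name] = "module1"
        elif i < s1 + s2:
            assignment[name] = "module2"
        else:
            assignment[name] = "background"
    truth = SyntheticTruth(
        de_genes=set(),
        effect_sizes={},
        module_assignment=assignment,
        hub_genes=hubs,
    )
    return graph, truth


# ---------------------------------------------------------------------------
# fixture bundle I/O

_BUNDLE_DEFAULTS = dict(
    n_genes=2000,
    n_pairs=30,
    effect_range=(1.0, 3.0),
    noise_sd=0.5,
    probes_per_gene=(1, 3),
    module_sizes=(86, 63),
    n_background=1296,  # main block of 1445 nodes
    p_in=0.3,
    p_out=0.003,
    n_hubs=20,
    hub_extra_degree=40,
    n_small_components=17,
)


def write_fixture_bundle(out_dir, seed: int = 0, **overrides) -> dict:
    """Write a coherent synthetic dataset bundle and return its manifest.

    Generates a planted PPI graph over a subset of the gene universe, then
    an expression matrix whose differential genes are exactly the graph's
    genes (so the DEG filter feeds the network stage, as when DEGs are
    submitted to a PPI database). Files: ``expression.tsv``,
    ``design.tsv``, ``probe_map.tsv``, ``edges.tsv``, ``truth.tsv`` and
    ``manifest.json``. Fixed seed => byte-identical files.
    """
    params = dict(_BUNDLE_DEFAULTS)
    params.update(overrides)
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(params["n_genes"])]
    graph, net_truth = generate_ppi(
        module_sizes=tuple(params["module_sizes"]),
        n_background=params["n_background"],
        p_in=params["p_in"],
        p_out=params["p_out"],
        n_hubs=params["n_hubs"],
        hub_extra_degree=params["hub_extra_degree"],
        n_small_components=params["n_small_components"],
        seed=int(rng.integers(2**31 - 1)),
        gene_names=genes,
    )
    expr, expr_truth = generate_expression(
        n_genes=params["n_genes"],
        n_pairs=params["n_pairs"],
        effect_range=tuple(params["effect_range"]),
        noise_sd=params["noise_sd"],
        probes_per_gene=tuple(params["probes_per_gene"]),
        seed=int(rng.integers(2**31 - 1)),
        gene_names=genes,
        de_genes=sorted(graph.nodes),
    )
    truth = expr_truth.merged_with(net_truth)
    # genes outside the graph stay "background" in the merged assignment
    for g in genes:
        truth.module_assignment.setdefault(g, "background")

    paths = {
        "expression": out_dir / "expression.tsv",
        "design": out_dir / "design.tsv",
        "probe_map": out_dir / "probe_map.tsv",
        "edges": out_dir / "edges.tsv",
        "truth": out_dir / "truth.tsv",
    }
    expr.values.to_csv(paths["expression"], sep="\t", index_label="probe")
    design = pd.DataFrame(
        {
            "sample": expr.design.index,
            "patient_condition": expr.design["patient"] + ":" + expr.design["condition"],
        }
    )
    design.to_csv(paths["design"], sep="\t", index=False)
    expr.probe_map.rename("gene").to_csv(paths["probe_map"], sep="\t", index_label="probe")

    edge_rows = sorted(graph.edges())
    scores = np.asarray(np.round(rng.uniform(400, 999, size=len(edge_rows))), dtype=int)
    pd.DataFrame(
        {
            "node1": [u for u, _ in edge_rows],
            "node2": [v for _, v in edge_rows],
            "combined_score": scores,
        }
    ).to_csv(paths["edges"], sep="\t", index=False)

    truth_frame = pd.DataFrame(
        {
            "gene": genes,
            "effect": [truth.effect_sizes.get(g, 0.0) for g in genes],
            "module": [truth.module_assignment[g] for g in genes],
            "is_hub": [int(g in truth.hub_genes) for g in genes],
        }
    )
    truth_frame.to_csv(paths["truth"], sep="\t", index=False)

    manifest = {
        "seed": seed,
        "parameters": {k: list(v) if isinstance(v, tuple) else v for k, v in params.items()},
        "files": {
            name: {"path": str(path), "n_rows": _count_data_rows(path)}
            for name, path in paths.items()
        },
        "n_graph_nodes": graph.n_nodes,
        "n_graph_edges": graph.n_edges,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _count_data_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh) - 1  # minus header


def read_expression(expression_path, design_path, probe_map_path) -> ExpressionMatrix:
    """Load an expression bundle written by :func:`write_fixture_bundle`."""
    values = pd.read_csv(expression_path, sep="\t", index_col="probe")
    design_raw = pd.read_csv(design_path, sep="\t", index_col="sample")
    split = design_raw["patient_condition"].str.split(":", expand=True)
    design = pd.DataFrame(
        {"patient": split[0], "condition": split[1]}, index=design_raw.index
    )
    probe_map = pd.read_csv(probe_map_path, sep="\t", index_col="probe")["gene"]
    return ExpressionMatrix(values=values, design=design, probe_map=probe_map)


def read_truth(path) -> SyntheticTruth:
    frame = pd.read_csv(path, sep="\t")
    effects = dict(zip(frame["gene"], frame["effect"].astype(float)))
    return SyntheticTruth(
        de_genes={g for g, e in effects.items() if e != 0.0},
        effect_sizes=effects,
        module_assignment=dict(zip(frame["gene"], frame["module"])),
        hub_genes=set(frame["gene"][frame["is_hub"] == 1]),
    )
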