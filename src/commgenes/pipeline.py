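"""End-to-end orchestration: config, staged run, manifest, report.

Stage order: differential expression -> probe collapse -> DEG selection ->
network build restricted to DEGs -> component summary (only the largest
connected component is carried forward) -> micro-level centrality ->
primary gene selection -> re-induction on the primary genes -> centrality
on the re-induced network -> Louvain modules -> per-module low-variance
metric exclusion -> per-module top gene selection -> intra-/inter-module
subnetworks -> optional gene-set over-representation. Every artifact is
plain TSV/JSON/GraphML and a ``manifest.json`` records versions, seed,
thresholds and per-stage counts; a failing stage writes a partial manifest
before the error propagates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, centrality, dge, network_io, selection, synthetic
from .containers import Partition, ThresholdSpec
from .enrichment import (
    inter_module_subnet,
    intra_module_subnet,
    ora_hypergeometric,
    read_gmt,
)
from .graph import Graph
from .modularity import louvain

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "report"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Exactly one of {real input paths, synthetic parameters} must be
    given: either all of ``expression/design/probe_map/edges`` or a
    ``synthetic`` mapping of generator overrides (may be empty to accept
    the generator defaults).
    """

    # inputs — real data
    expression: str | None = None
    design: str | None = None
    probe_map: str | None = None
    edges: str | None = None
    # inputs — synthetic generation
    synthetic: dict | None = None

    # DEG cutoffs
    p_max: float = 0.01
    fdr_max: float = 0.01
    min_abs_logfc: float = 1.0
    top_n: int = 2000

    # network build
    min_combined_score: float = 0.4

    # primary selection: explicit thresholds win over auto-tuning
    primary_thresholds: dict | None = None
    primary_metrics: tuple = ("degree", "stress", "eigenvector")
    primary_target_fraction: float = 0.10

    # macro level
    resolution: float = 1.0
    seed: int = 0
    rel_var_min: float = 0.05
    module_metrics: tuple = ("degree", "stress", "betweenness", "eigenvector")
    module_thresholds: dict | None = None  # module id (int or str) -> {metric: thr}
    module_target_fraction: float = 0.10

    # enrichment
    gmt: str | None = None

    outdir: str = "commgenes_run"

    def validate(self) -> None:
        real = [self.expression, self.design, self.probe_map, self.edges]
        has_real = all(p is not None for p in real)
        some_real = any(p is not None for p in real)
        has_syn = self.synthetic is not None
        if has_syn and some_real:
            raise ConfigError("give either real input paths or synthetic parameters, not both")
        if not has_syn and not has_real:
            raise ConfigError(
                "incomplete inputs: need all of expression/design/probe_map/edges "
                "or a synthetic section"
            )
        for name in ("p_max", "fdr_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.min_abs_logfc < 0:
            raise ConfigError("min_abs_logfc must be non-negative")
        if self.top_n <= 0:
            raise ConfigError("top_n must be positive")
        if not 0 <= self.min_combined_score <= 1:
            raise ConfigError("min_combined_score must lie in [0, 1]")
        if not 0 < self.primary_target_fraction < 1:
            raise ConfigError("primary_target_fraction must lie in (0, 1)")
        if not 0 < self.module_target_fraction < 1:
            raise ConfigError("module_target_fraction must lie in (0, 1)")
        if self.resolution <= 0:
            raise ConfigError("resolution must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("primary_metrics", "module_metrics"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        config.validate()
        return config


def _write_tsv(frame: pd.DataFrame, path: Path, index_label="node") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the workflow; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "commgenes": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "status": "running",
    }

    def finish_stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    def write_manifest() -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )

    current_stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        current_stage = "inputs"
        if config.synthetic is not None:
            bundle_dir = outdir / "synthetic_input"
            synthetic.write_fixture_bundle(
                bundle_dir, seed=config.seed, **config.synthetic
            )
            expr = synthetic.read_expression(
                bundle_dir / "expression.tsv",
                bundle_dir / "design.tsv",
                bundle_dir / "probe_map.tsv",
            )
            edges_path = bundle_dir / "edges.tsv"
        else:
            expr = synthetic.read_expression(
                config.expression, config.design, config.probe_map
            )
            edges_path = config.edges
        finish_stage("inputs", n_probes=len(expr.values), n_samples=expr.values.shape[1])

        # ---- differential expression ------------------------------------
        current_stage = "dge"
        probe_table = dge.moderated_paired_t(expr)
        gene_table = dge.collapse_probes(probe_table, expr.probe_map)
        _write_tsv(gene_table, outdir / "dge_table.tsv", index_label="gene")
        degs = dge.select_degs(
            gene_table,
            p_max=config.p_max,
            fdr_max=config.fdr_max,
            min_abs_logfc=config.min_abs_logfc,
            top_n=config.top_n,
        )
        _write_tsv(degs, outdir / "degs.tsv", index_label="gene")
        finish_stage("dge", n_genes=len(gene_table), n_degs=len(degs))

        # ---- network build ----------------------------------------------
        current_stage = "network"
        full_graph = network_io.read_string_edges(
            edges_path, min_combined_score=config.min_combined_score
        )
        deg_graph = network_io.induced_subgraph(full_graph, set(degs.index))
        summary = network_io.summarize_components(deg_graph)
        (outdir / "component_summary.json").write_text(
            json.dumps(asdict(summary), indent=2)
        )
        network_io.write_edges(deg_graph, outdir / "deg_network.tsv")
        network_io.write_graphml(deg_graph, outdir / "deg_network.graphml")
        components = network_io.connected_components(deg_graph)
        if not components:
            raise ValueError("DEG network is empty; nothing to analyze")
        main_component = deg_graph.subgraph(components[0])
        finish_stage(
            "network",
            n_nodes=deg_graph.n_nodes,
            n_edges=deg_graph.n_edges,
            n_components=summary.n_components,
            main_component_size=main_component.n_nodes,
        )

        # ---- micro-level metrics + primary selection --------------------
        current_stage = "primary_selection"
        table_main = centrality.compute_all(main_component)
        _write_tsv(table_main, outdir / "centrality_main.tsv")
        if config.primary_thresholds is not None:
            primary_spec = ThresholdSpec(
                min_values={k: float(v) for k, v in config.primary_thresholds.items()}
            )
        else:
            primary_spec, _ = selection.tune_thresholds(
                table_main,
                metrics=config.primary_metrics,
                target_fraction=config.primary_target_fraction,
            )
        primary = selection.select_primary(table_main, primary_spec)
        _write_tsv(primary.to_frame(), outdir / "primary_selection.tsv")
        (outdir / "primary_selection.json").write_text(
            json.dumps({"counts": primary.counts, **primary.provenance}, indent=2)
        )
        finish_stage("primary_selection", **primary.counts)

        # ---- re-induction + macro level ---------------------------------
        current_stage = "reinduction"
        primary_graph = network_io.induced_subgraph(main_component, primary.combined)
        network_io.write_edges(primary_graph, outdir / "primary_network.tsv")
        network_io.write_graphml(primary_graph, outdir / "primary_network.graphml")
        table_primary = centrality.compute_all(primary_graph)
        _write_tsv(table_primary, outdir / "centrality_primary.tsv")
        singletons = {n for n in primary_graph.nodes if primary_graph.degree(n) == 0}
        connected_part = primary_graph.subgraph(primary_graph.nodes - singletons)
        finish_stage(
            "reinduction",
            n_nodes=primary_graph.n_nodes,
            n_edges=primary_graph.n_edges,
            n_singletons=len(singletons),
        )

        current_stage = "modularity"
        partition = louvain(
            connected_part, resolution=config.resolution, seed=config.seed
        )
        part_frame = pd.DataFrame(
            {"module": [partition.assignment[n] for n in sorted(partition.assignment)]},
            index=pd.Index(sorted(partition.assignment), name="node"),
        )
        _write_tsv(part_frame, outdir / "partition.tsv")
        (outdir / "partition.json").write_text(
            json.dumps(
                {
                    "q": partition.q,
                    "level_qs": partition.level_qs,
                    "resolution": config.resolution,
                    "seed": config.seed,
                    "module_sizes": partition.module_sizes(),
                    "excluded_singletons": sorted(singletons),
                },
                indent=2,
            )
        )
        finish_stage(
            "modularity",
            n_modules=partition.n_modules,
            q=round(partition.q, 6),
            **{f"module_{m}_size": s for m, s in sorted(partition.module_sizes().items())},
        )

        # ---- per-module top selection -----------------------------------
        current_stage = "top_selection"
        top_sets: dict[int, selection.SelectionResult] = {}
        for module in sorted(set(partition.assignment.values())):
            members = sorted(partition.members(module))
            sub_table = table_primary.loc[members]
            if len(sub_table) < 2:
                logger.info("module %d too small for top selection", module)
                continue
            excluded = selection.low_variance_metrics(
                sub_table, rel_var_min=config.rel_var_min, metrics=config.module_metrics
            )
            usable = [m for m in config.module_metrics if m not in excluded]
            explicit = None
            if config.module_thresholds is not None:
                explicit = config.module_thresholds.get(
                    module, config.module_thresholds.get(str(module))
                )
            if explicit is not None:
                spec = ThresholdSpec(
                    min_values={
                        k: float(v) for k, v in explicit.items() if k not in excluded
                    }
                )
            elif usable:
                spec, _ = selection.tune_thresholds(
                    sub_table,
                    metrics=usable,
                    target_fraction=config.module_target_fraction,
                )
            else:
                logger.warning("module %d: all metrics excluded as low-variance", module)
                continue
            result = selection.select_top_in_module(sub_table, spec)
            top_sets[module] = result
            _write_tsv(result.to_frame(), outdir / f"top_module{module}.tsv")
            (outdir / f"top_module{module}.json").write_text(
                json.dumps(
                    {
                        "counts": result.counts,
                        "excluded_metrics": excluded,
                        **result.provenance,
                    },
                    indent=2,
                )
            )
        finish_stage(
            "top_selection",
            **{f"module_{m}_top": r.counts["combined"] for m, r in sorted(top_sets.items())},
        )

        # ---- subnetworks -------------------------------------------------
        current_stage = "subnets"
        for module, result in sorted(top_sets.items()):
            subnet = intra_module_subnet(
                primary_graph, result.combined, partition.members(module)
            )
            network_io.write_edges(subnet, outdir / f"subnet_intra_module{module}.tsv")
            network_io.write_graphml(
                subnet, outdir / f"subnet_intra_module{module}.graphml"
            )
        inter_counts: dict[str, int] = {}
        by_size = sorted(
            top_sets, key=lambda m: (-len(partition.members(m)), m)
        )
        if len(by_size) >= 2:
            m1, m2 = by_size[:2]
            inter = inter_module_subnet(
                primary_graph, top_sets[m1].combined, top_sets[m2].combined
            )
            inter_frame = pd.DataFrame(
                [
                    {"node1": u, "node2": v, "edge_class": c}
                    for (u, v), c in sorted(inter.edge_classes.items())
                ],
                columns=["node1", "node2", "edge_class"],
            )
            inter_frame.to_csv(outdir / "subnet_inter.tsv", sep="\t", index=False)
            inter_counts = inter.class_counts()
        finish_stage("subnets", **inter_counts)

        # ---- enrichment (optional) --------------------------------------
        if config.gmt is not None:
            current_stage = "enrichment"
            collection = read_gmt(config.gmt)
            background = set(main_component.nodes)
            study = set().union(*(r.combined for r in top_sets.values())) & background
            enr = ora_hypergeometric(study, collection, background)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            finish_stage(
                "enrichment",
                n_sets=len(collection),
                n_significant=int((enr["fdr"] < 0.05).sum()) if not enr.empty else 0,
            )

        manifest["status"] = "ok"
        write_manifest()
        return outdir
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        write_manifest()
        raise StageError(current_stage, exc) from exc


_REPORT_STAGES = [
    "inputs",
    "dge",
    "network",
    "primary_selection",
    "reinduction",
    "modularity",
    "top_selection",
    "subnets",
    "enrichment",
]


def report(run_dir) -> str:
    """Human-readable markdown summary of a run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# commgenes run report",
        "",
        f"- status: **{manifest.get('status', 'unknown')}**",
        f"- seed: {manifest.get('seed')}",
        f"- package version: {manifest['versions']['commgenes']}",
        "",
        "## Stage counts",
        "",
    ]
    stages = manifest.get("stages", {})
    for stage in _REPORT_STAGES:
        if stage in stages:
            counts = ", ".join(f"{k}={v}" for k, v in stages[stage].items())
            lines.append(f"- {stage}: {counts}")
        elif stage != "enrichment":  # enrichment is optional
            lines.append(f"- {stage}: MISSING")
    if manifest.get("status") == "failed":
        lines += ["", f"Run aborted at stage `{manifest.get('failed_stage')}`: "
                      f"{manifest.get('error')}"]

    partition_path = run_dir / "partition.json"
    dge_path = run_dir / "dge_table.tsv"
    part_tsv = run_dir / "partition.tsv"
    if partition_path.exists() and part_tsv.exists():
        part_meta = json.loads(partition_path.read_text())
        lines += ["", "## Modules", "",
                  f"- modularity Q = {part_meta['q']:.4f} "
                  f"(resolution {part_meta['resolution']}, seed {part_meta['seed']})"]
        part = pd.read_csv(part_tsv, sep="\t", index_col="node")
        if dge_path.exists():
            dge_table = pd.read_csv(dge_path, sep="\t", index_col="gene")
            for module, members in part.groupby("module").groups.items():
                logfc = dge_table.reindex(members)["logFC"].dropna()
                lines.append(
                    f"- module {module}: {len(members)} genes "
                    f"({int((logfc > 0).sum())} up, {int((logfc < 0).sum())} down)"
                )
    top_files = sorted(run_dir.glob("top_module*.tsv"))
    if top_files:
        lines += ["", "## Top communicative genes", ""]
        for path in top_files:
            top = pd.read_csv(path, sep="\t", index_col="node")
            lines.append(f"- {path.stem}: {', '.join(sorted(top.index))}")
    missing = [
        s for s in _REPORT_STAGES[:-1] if s not in stages
    ]
    if missing:
        lines += ["", f"Missing stages: {', '.join(missing)}"]
    return "\n".join(lines) + "\n"
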