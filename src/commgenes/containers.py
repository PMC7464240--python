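"""Shared in-memory containers for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("NL", "LL")  # non-lesional (reference) / lesional (case)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 expression with a paired two-condition design.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows indexed by probe ID, columns by
        sample ID.
    design
        DataFrame indexed by sample ID with columns ``patient`` and
        ``condition`` (``"NL"`` or ``"LL"``). Every patient must contribute
        exactly one sample per condition.
    probe_map
        Series mapping probe ID -> gene symbol; many probes may map to one
        gene.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    probe_map: pd.Series

    def validate(self) -> None:
        if set(self.design.index) != set(self.values.columns):
            raise ValueError("design samples do not match expression columns")
        bad_cond = set(self.design["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        counts = self.design.groupby("patient")["condition"].agg(
            lambda c: tuple(sorted(c))
        )
        for patient, conds in counts.items():
            if conds != ("LL", "NL"):
                raise ValueError(
                    f"patient {patient!r} is not paired: has conditions {list(conds)}"
                )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values contain missing or non-finite entries")

    @property
    def patients(self) -> list:
        return sorted(self.design["patient"].unique())

    def paired_diffs(self) -> pd.DataFrame:
        """Per-probe LL − NL differences, one column per patient."""
        by_cond = {}
        for cond in CONDITIONS:
            sub = self.design[self.design["condition"] == cond]
            samples = sub.index.to_series().groupby(sub["patient"]).first()
            by_cond[cond] = self.values[samples.loc[self.patients]]
        diff = by_cond["LL"].to_numpy() - by_cond["NL"].to_numpy()
        return pd.DataFrame(diff, index=self.values.index, columns=self.patients)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``effect_sizes`` maps every generated gene to its true log2 fold change
    (0.0 for non-differential genes); ``module_assignment`` maps every gene
    to ``"module1"``, ``"module2"`` or ``"background"``.
    """

    de_genes: set = field(default_factory=set)
    effect_sizes: dict = field(default_factory=dict)
    module_assignment: dict = field(default_factory=dict)
    hub_genes: set = field(default_factory=set)

    def merged_with(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            de_genes=self.de_genes | other.de_genes,
            effect_sizes={**other.effect_sizes, **self.effect_sizes},
            module_assignment={**self.module_assignment, **other.module_assignment},
            hub_genes=self.hub_genes | other.hub_genes,
        )


@dataclass
class ComponentSummary:
    """Connected-component profile of a graph.

    ``total_connected_nodes`` counts nodes in components of size >= 2
    (degree >= 1); singletons are reported separately.
    """

    n_components: int
    size_histogram: dict[int, int]
    largest_size: int
    total_connected_nodes: int
    n_singletons: int


@dataclass
class Partition:
    """Node -> module assignment with its modularity score Q."""

    assignment: dict
    q: float
    level_qs: list[float] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module: int) -> set:
        return {n for n, m in self.assignment.items() if m == module}

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes


@dataclass
class ThresholdSpec:
    """Per-metric minimum values for centrality-based gene selection.

    Comparisons downstream are inclusive (value >= threshold). An optional
    ``target_fraction`` records the union-size target used when thresholds
    were auto-tuned.
    """

    min_values: dict[str, float] = field(default_factory=dict)
    target_fraction: float | None = None

    def __post_init__(self) -> None:
        for metric, thr in self.min_values.items():
            if thr < 0:
                raise ValueError(f"negative threshold for {metric!r}: {thr}")
        if self.target_fraction is not None and not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must lie in (0, 1)")


@dataclass
class SelectionResult:
    """Outcome of thresholding a centrality table."""

    per_metric: dict[str, frozenset]
    combined: frozenset
    counts: dict[str, int]
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        """Flag table: one row per selected node, one column per metric."""
        nodes = sorted(self.combined)
        data = {
            metric: [n in sel for n in nodes] for metric, sel in self.per_metric.items()
        }
        frame = pd.DataFrame(data, index=pd.Index(nodes, name="node"))
        frame["combined"] = True
        return frame
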