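"""Centrality-threshold gene selection.

Two selection stages share the same machinery: *primary* communicative
genes are chosen on the full DEG network by inclusive per-metric minimum
thresholds combined by set UNION, and *top* communicative genes are chosen
per module on the re-induced network the same way, after metrics whose
values barely vary inside the module have been excluded (a near-constant
metric cannot discriminate).

Union semantics: a gene passing any single metric threshold enters the
combined set. Thresholds can be given explicitly (the usual mode for a
published replication) or auto-tuned: a common per-metric quantile is
lowered stepwise until the union strictly exceeds a target fraction of the
nodes (e.g. "more than 10 percent of the network").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import SelectionResult, ThresholdSpec

__all__ = [
    "select_primary",
    "select_top_in_module",
    "tune_thresholds",
    "low_variance_metrics",
]


def _select(table: pd.DataFrame, spec: ThresholdSpec, stage: str) -> SelectionResult:
    if not spec.min_values:
        warnings.warn(
            f"{stage}: empty threshold spec selects nothing", stacklevel=3
        )
    per_metric: dict[str, frozenset] = {}
    for metric, thr in spec.min_values.items():
        if metric not in table.columns:
            raise KeyError(f"{stage}: metric {metric!r} absent from centrality table")
        per_metric[metric] = frozenset(table.index[table[metric] >= thr])
    combined: frozenset = frozenset().union(*per_metric.values()) if per_metric else frozenset()
    counts = {m: len(s) for m, s in per_metric.items()}
    counts["combined"] = len(combined)
    return SelectionResult(
        per_metric=per_metric,
        combined=combined,
        counts=counts,
        provenance={
            "stage": stage,
            "thresholds": dict(spec.min_values),
            "target_fraction": spec.target_fraction,
            "n_nodes": int(len(table)),
        },
    )


def select_primary(table: pd.DataFrame, spec: ThresholdSpec) -> SelectionResult:
    """Primary communicative genes: per-metric inclusive thresholds, union."""
    return _select(table, spec, stage="primary")


def select_top_in_module(table: pd.DataFrame, spec: ThresholdSpec) -> SelectionResult:
    """Top communicative genes within one module (same union semantics)."""
    return _select(table, spec, stage="module-top")


def tune_thresholds(
    table: pd.DataFrame,
    metrics,
    target_fraction: float = 0.10,
    q_start: float = 0.99,
    q_step: float = 0.005,
) -> tuple[ThresholdSpec, int]:
    """Find per-metric thresholds whose union exceeds a node fraction.

    All metrics share one quantile ``q``, lowered from ``q_start`` in steps
    of ``q_step`` until the union of per-metric selections strictly exceeds
    ``target_fraction * n``. Returns the spec and the achieved union size.
    """
    if table.empty:
        raise ValueError("cannot tune thresholds on an empty table")
    metrics = list(metrics)
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise KeyError(f"metrics absent from table: {missing}")
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    n = len(table)
    target = target_fraction * n
    q = q_start
    while True:
        thresholds = {m: float(np.quantile(table[m].to_numpy(), q)) for m in metrics}
        spec = ThresholdSpec(min_values=thresholds, target_fraction=target_fraction)
        result = _select(table, spec, stage="tune")
        if result.counts["combined"] > target:
            return spec, result.counts["combined"]
        if q <= 0:
            raise ValueError(
                f"target fraction {target_fraction} unreachable: union "
                f"{result.counts['combined']} of {n} at quantile 0"
            )
        q = max(0.0, q - q_step)


def low_variance_metrics(
    table: pd.DataFrame, rel_var_min: float = 0.05, metrics=None
) -> list[str]:
    """Metrics too flat to discriminate within a module.

    A metric is excluded when all its values are equal or its coefficient
    of variation (sd/mean, for positive mean) falls below ``rel_var_min``.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to assess metric variance")
    metrics = list(metrics) if metrics is not None else list(table.columns)
    excluded = []
    for metric in metrics:
        values = table[metric].to_numpy(dtype=float)
        if np.all(values == values[0]):
            excluded.append(metric)
            continue
        mean = values.mean()
        if mean > 0 and values.std(ddof=1) / mean < rel_var_min:
            excluded.append(metric)
    return excluded
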