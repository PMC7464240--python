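"""Paired-design differential expression with an empirical-Bayes moderated t.

The moderated t-test shrinks each probe's paired-difference variance toward
a common prior estimated across all probes, which stabilizes the statistic
when the number of pairs is small relative to the number of probes. The
hierarchical model is the classical scaled-inverse-chi-squared prior on the
true variances: given a prior with ``d0`` degrees of freedom and scale
``s0^2``, the posterior variance for probe g with sample variance ``s_g^2``
on ``d_g`` residual degrees of freedom is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t ``logFC_g / (s~_g / sqrt(n))`` follows a t distribution
with ``d0 + d_g`` degrees of freedom under the null. The hyperparameters
(d0, s0^2) are estimated by the method of moments on ``log s_g^2`` using the
exact digamma/trigamma moments of the log chi-squared distribution. When
the observed spread of ``log s_g^2`` does not exceed its pure sampling
component the moment equation has no finite solution; the prior degrees of
freedom are then infinite and every posterior variance collapses to the
geometric mean of the sample variances (complete shrinkage).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import ExpressionMatrix

__all__ = ["moderated_paired_t", "bh_adjust", "select_degs", "collapse_probes"]

DGE_COLUMNS = ["logFC", "t_mod", "p", "fdr", "df_total"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d_resid: int) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) of the inverse-chi-squared variance prior.

    Uses probes with strictly positive sample variance. Returns
    ``d0 = inf`` with ``s0^2`` equal to the geometric mean of the positive
    sample variances when the moment equation has no finite solution, so
    that identical sample variances shrink to themselves exactly.
    """
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError(
            "all probes have zero variance across pairs; "
            "variance-prior estimation is undefined"
        )
    z = np.log(positive)
    half_d = d_resid / 2.0
    if z.size < 2:
        return math.inf, float(np.exp(z.mean()))
    evar = float(np.var(z, ddof=1)) - float(polygamma(1, half_d))
    if evar <= 0:
        return math.inf, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    log_s02 = (
        float(z.mean())
        - float(digamma(half_d))
        + math.log(half_d)
        + float(digamma(d0 / 2.0))
        - math.log(d0 / 2.0)
    )
    return d0, float(math.exp(log_s02))


def moderated_paired_t(
    expr: ExpressionMatrix, prior_df: float | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test, one row per probe.

    Parameters
    ----------
    expr
        Paired expression matrix (validated: each patient one NL and one LL
        sample, at least two pairs).
    prior_df
        Override for the prior degrees of freedom ``d0``. ``None`` (default)
        estimates it by the method of moments; ``0`` disables shrinkage and
        reproduces the classical paired t exactly; ``inf`` forces complete
        shrinkage.

    Returns
    -------
    DataFrame indexed by probe with columns ``logFC, t_mod, p, fdr,
    df_total``.
    """
    expr.validate()
    diffs = expr.paired_diffs()
    n = diffs.shape[1]
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = diffs.to_numpy()
    logfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    d_resid = n - 1

    if prior_df is None:
        d0, s02 = _fit_variance_prior(s2, d_resid)
    elif prior_df == 0:
        d0, s02 = 0.0, float("nan")  # scale unused when d0 = 0
    else:
        d0 = float(prior_df)
        _, s02 = _fit_variance_prior(s2, d_resid)

    if math.isinf(d0):
        post_var = np.full_like(s2, s02)
    elif d0 == 0:
        post_var = s2
    else:
        post_var = (d0 * s02 + d_resid * s2) / (d0 + d_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / np.sqrt(post_var / n)
    t_mod = np.where((post_var == 0) & (logfc == 0), 0.0, t_mod)

    df_total = d0 + d_resid
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "p": p,
            "fdr": bh_adjust(p),
            "df_total": df_total,
        },
        index=expr.values.index,
    )
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def select_degs(
    table: pd.DataFrame,
    p_max: float = 0.01,
    fdr_max: float = 0.01,
    min_abs_logfc: float = 1.0,
    top_n: int = 2000,
) -> pd.DataFrame:
    """Apply significance cutoffs and keep at most ``top_n`` rows.

    Rows must satisfy ``p < p_max``, ``fdr < fdr_max`` (strict) and
    ``|logFC| >= min_abs_logfc`` (inclusive). Survivors are ranked by
    ascending FDR, ties broken by descending |logFC| and then by row ID,
    and truncated to ``top_n``.
    """
    for col in ("p", "fdr", "logFC"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    passing = table[
        (table["p"] < p_max)
        & (table["fdr"] < fdr_max)
        & (table["logFC"].abs() >= min_abs_logfc)
    ].copy()
    passing["_neg_abs_lfc"] = -passing["logFC"].abs()
    passing["_id"] = passing.index.astype(str)
    passing = passing.sort_values(["fdr", "_neg_abs_lfc", "_id"], kind="mergesort")
    return passing.drop(columns=["_neg_abs_lfc", "_id"]).head(top_n)


def collapse_probes(table: pd.DataFrame, probe_map) -> pd.DataFrame:
    """Collapse a probe-keyed table to genes by the max-|logFC| rule.

    For each gene the retained row is the probe whose |logFC| is maximal
    (signed value, p and FDR carried along); |logFC| ties go to the
    lexicographically smallest probe ID. Idempotent when the table is
    already gene-keyed and ``probe_map`` is the identity.
    """
    probe_map = pd.Series(dict(probe_map)) if not isinstance(probe_map, pd.Series) else probe_map
    missing = [p for p in table.index if p not in probe_map.index]
    if missing:
        raise KeyError(f"probes missing from probe map: {missing[:10]}" +
                       (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
    work = table.copy()
    work["_gene"] = probe_map.loc[table.index].to_numpy()
    work["_neg_abs_lfc"] = -work["logFC"].abs()
    work["_probe"] = work.index.astype(str)
    work = work.sort_values(["_neg_abs_lfc", "_probe"], kind="mergesort")
    collapsed = work.drop_duplicates("_gene", keep="first")
    collapsed = collapsed.set_index("_gene").sort_index()
    collapsed.index.name = "gene"
    return collapsed.drop(columns=["_neg_abs_lfc", "_probe"])
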