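# Methods

This note records the models, conventions and design decisions behind
`commgenes`, in the spirit of a statistical methods appendix: what each
stage assumes, which knobs matter, and what the synthetic benchmarks do
and do not demonstrate.

## Moderated paired t-test

**Model.** For probe *g* with paired differences over *n* patients,
`logFC_g = mean(d)` and sample variance `s_g²` on `d_g = n − 1` degrees of
freedom. True variances follow a scaled inverse-chi-squared prior with
scale `s₀²` and `d₀` degrees of freedom; the posterior variance is the
precision-weighted blend `s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)` and
`t̃ = logFC/(s̃/√n)` is referred to a t distribution with `d₀ + d_g`
degrees of freedom (normal when `d₀ = ∞`).

**Hyperparameter estimation.** Method of moments on `z = log s_g²` using
the exact log-chi-squared moments: the excess of `var(z)` over the pure
sampling term `ψ′(d_g/2)` identifies `d₀` through a trigamma inversion
(Newton iteration), and the mean of `z` then identifies `s₀²` after
digamma bias correction. Probes with `s_g² = 0` are excluded from
estimation but still receive a posterior variance (finite, positive
whenever `d₀ > 0`), so constant-difference probes get a large finite t
rather than ∞. If *every* probe has zero variance the fit is undefined
and rejected with an error.

**Degenerate branch.** When `var(z)` does not exceed its sampling
component the moment equation has no finite solution; we set `d₀ = ∞` and
`s₀² = exp(mean(z))` — the *geometric mean* of the sample variances,
without the digamma correction. This choice makes the no-information case
exact: when all probes share one sample variance, complete shrinkage
returns exactly that variance and the moderated t coincides with the
classical paired t to machine precision. The cost is a mild (~2% at
n = 30) anti-conservatism in the rare fully-degenerate regime, visible as
a null p < 0.05 rate of ≈ 0.053 rather than 0.050 in the calibration
benchmark; with heterogeneous variances the finite-`d₀` branch applies
and is correctly calibrated. `prior_df=0` disables shrinkage entirely
(classical t), useful for sensitivity checks.

**Cutoffs.** Defaults `p < 0.01`, BH-FDR `< 0.01` (both strict),
`|logFC| ≥ 1` (inclusive), top 2000 — the published settings. The top-N
ranking (ascending FDR, ties by descending |logFC|, then row ID) is our
declared convention; the original study does not state its ranking
statistic. Probe collapse keeps the signed logFC of the max-|logFC| probe
(ties to the lexicographically smallest probe ID) so up/down calls remain
possible downstream.

## Network conventions

Graphs are undirected, unweighted and simple; edge confidence is used
only for thresholding (inclusive `combined_score ≥ 0.4` by default, with
automatic detection of the 0–1000 integer serialization). "Connected
nodes" means degree ≥ 1; singletons are counted separately. Only the
largest connected component enters centrality-based selection — smaller
components are summarized and reported, matching how hub screens treat
stray doublets and triplets.

## Centrality conventions

The published value ranges fix the normalizations: degree and stress are
reported raw (integer counts), betweenness is normalized per component by
`(n−1)(n−2)/2` to [0, 1], closeness is the within-component
`(n−1)/Σd`, and the eigenvector is L2-normalized per component.
Betweenness and stress come from a single Brandes-style accumulation:
alongside the classical pair-dependency `δ`, an integer counter
`φ(v) = Σ_{w: v∈pred(w)} (1 + φ(w))` counts shortest-path suffixes, and
`σ_sv·φ(v)` summed over sources (halved for unordered pairs) is exactly
the stress. Path counts are Python integers, so stress is exact at any
graph size. The eigenvector uses power iteration on `A + I`; the shift
leaves eigenvectors unchanged while guaranteeing a simple dominant
eigenvalue on connected (including bipartite) components. Default
`tol = 1e−13` on successive iterates, `max_iter = 100 000`;
non-convergence raises with the residual.

## Modularity and Louvain

`Q = Σ_c [e_c/m − γ(d_c/2m)²]` with resolution `γ = 1` by default (the
case study reports two modules at default settings; γ is exposed for
sensitivity analysis). The Louvain implementation follows the standard
two-phase scheme; sweep order is shuffled from one explicit seed,
equal-gain ties go to the lowest module id, and each level's Q is
recomputed from scratch on the original graph (recorded in `level_qs`,
non-decreasing by construction). Exact module membership is inherently
seed-dependent; benchmarks therefore assert planted-partition recovery
(NMI ≥ 0.95 on 75+75 blocks with p_in = 0.3, p_out = 0.01) rather than a
specific labeling.

## Selection logic

Per-metric comparisons are inclusive (≥) and per-metric sets combine by
**union**. The union convention is deliberate: in the case study's
module-1 table the six reported top genes are exactly the union of the
three printed metric groups (their intersection would be two genes), so
union is the behavior that reproduces the published outcome.
Auto-tuning lowers a single shared quantile from 0.99 in steps of 0.005
until the union strictly exceeds the target fraction (default 10%);
explicit thresholds always take precedence. Within modules, metrics with
coefficient of variation below `rel_var_min = 0.05` (or exactly constant)
are excluded before selection — the study describes "very low variance"
without a numeric criterion, so 0.05 is our declared default.

## Over-representation

Upper-tail hypergeometric p-values per GMT set, sets intersected with the
background first. The background defaults to the analyzed network's gene
set, not the genome, because the tested study sets are drawn from network
nodes; BH adjustment shares the DGE implementation. Enrichr-style
combined scores are out of scope — rows are ranked by p.

## Synthetic data: what it emulates, what it does not

The expression generator mimics normalized log2 microarray intensities:
gene baselines N(8, 2²), probe offsets N(0, 0.25²), a patient-level shift
N(0, 0.5²) shared by both conditions (removed by pairing), i.i.d. noise
(default sd 0.5), and additive true log2 fold changes (default magnitudes
uniform on [1, 3], random sign) on a chosen fraction of genes. The graph
generator plants two dense blocks (default sizes 86 and 63, the case
study's module cardinalities), sparse background, hub nodes with extra
random attachments, and small 2–3-node path components. The bundle writer
couples the two by making the graph's genes exactly the differential
genes, mirroring DEG submission to a PPI database. Defaults (2000 genes,
30 pairs, a 1445-node main block, 17 small components) are a desk-scale
rendition of the study's dimensions (54 675 probes, 85 pairs, 1445-node
component); the full-scale run completes in seconds.

Not emulated: probe-level preprocessing (MAS 5.0, QC), batch effects,
heavy-tailed or correlated noise, degree-corrected or overlapping
community structure, and score heterogeneity among retained edges. A
passing benchmark therefore shows the algorithms are correct and
well-calibrated under the stated generative model, not that the
biological conclusions of any particular study transfer.

The separate "super-hub" demonstration dataset wires designated hubs to
every member of their module (degree ≥ 39 vs ≤ ~20 for non-hubs) with a
single inter-module bridge, so the planted top sets dominate every metric
by a wide margin and the pipeline must recover them exactly — an
end-to-end identifiability check, not a realistic network.

## Numerical and degenerate-input choices

* BH adjustment: stable mergesort ranks; tied p-values receive identical
  adjusted values; permutation-equivariant.
* `tune_thresholds` always terminates for target fractions < 1 (at
  quantile 0, all nodes are selected) and asserts the target on exit.
* Empty threshold specs warn and select nothing; metrics named in a spec
  but absent from the table raise naming the metric.
* Eigenvector centrality of singleton components is defined as 1.0;
  closeness of isolated nodes as 0; betweenness is 0 for components of
  size < 3.
* Self-loops are rejected at graph construction; STRING self-pairs are
  dropped with a log message; duplicate/reversed pairs collapse.
* Modularity requires at least one edge; Louvain additionally excludes
  re-induction singletons at the pipeline level (they are reported, not
  clustered).

## Known limitations

* The moderated-t degenerate branch trades a small calibration bias for
  exactness in the equal-variance limit (see above).
* Stress and betweenness are O(n·m) per graph in pure Python; the
  ~1450-node default scale runs in seconds, but graphs beyond ~10⁴ nodes
  would need a compiled backend.
* The study's published 152-gene and 17-gene lists depend on its exact
  GEO series and STRING release and are not reproducible from synthetic
  data; the shipped reference tables anchor the *selection logic* (which
  thresholds produce which published sets), not the upstream data.
* Louvain is a heuristic: Q is locally, not globally, optimal, and
  module ids are arbitrary (stable only at fixed seed).
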