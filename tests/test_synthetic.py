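import numpy as np
import pandas as pd
import pytest

from commgenes import dge
from commgenes.network_io import connected_components, read_string_edges
from commgenes.synthetic import (
    generate_expression,
    generate_ppi,
    read_expression,
    read_truth,
    write_fixture_bundle,
)


class TestGenerateExpression:
    def test_seeded_reproducibility(self):
        a, _ = generate_expression(50, 5, seed=42)
        b, _ = generate_expression(50, 5, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.design, b.design)

    def test_null_construction(self):
        expr, truth = generate_expression(400, 20, de_fraction=0.0, seed=1)
        assert truth.de_genes == set()
        diffs = expr.paired_diffs()
        # mean LL-NL is 0 in expectation: grand mean within a few SEs
        se = diffs.to_numpy().std() / np.sqrt(diffs.size)
        assert abs(diffs.to_numpy().mean()) < 4 * se

    def test_de_genes_have_stated_effects(self):
        expr, truth = generate_expression(
            200, 10, de_fraction=0.3, effect_range=(1.0, 3.0), seed=7
        )
        assert truth.de_genes <= set(truth.effect_sizes)
        for g in truth.de_genes:
            assert 1.0 <= abs(truth.effect_sizes[g]) <= 3.0
        for g, e in truth.effect_sizes.items():
            assert (e != 0) == (g in truth.de_genes)

    def test_multi_probe_genes_exist(self):
        expr, _ = generate_expression(30, 4, probes_per_gene=(1, 3), seed=0)
        counts = expr.probe_map.value_counts()
        assert (counts >= 2).any()
        assert len(expr.values) == len(expr.probe_map)

    def test_paired_design_valid(self):
        expr, _ = generate_expression(20, 6, seed=3)
        expr.validate()  # does not raise
        assert expr.values.shape == (len(expr.probe_map), 12)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_genes=0, n_pairs=5), "n_genes"),
            (dict(n_genes=10, n_pairs=0), "n_pairs"),
            (dict(n_genes=10, n_pairs=5, de_fraction=1.5), "de_fraction"),
            (dict(n_genes=10, n_pairs=5, noise_sd=0.0), "noise_sd"),
        ],
    )
    def test_rejects_bad_parameters_naming_them(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            generate_expression(**kwargs)

    def test_deg_recovery_power(self):
        """Moderated t at the standard cutoffs recovers nearly all planted
        DE genes at the pilot-calibrated parameter point."""
        sens = []
        for seed in range(3):
            expr, truth = generate_expression(
                1000, 85, de_fraction=0.2, effect_range=(1, 3),
                noise_sd=0.5, seed=seed,
            )
            table = dge.moderated_paired_t(expr)
            genes = dge.collapse_probes(table, expr.probe_map)
            degs = dge.select_degs(genes)
            sens.append(len(set(degs.index) & truth.de_genes) / len(truth.de_genes))
        assert np.mean(sens) >= 0.95


class TestGeneratePPI:
    def test_no_cross_edges_gives_planted_component_count(self):
        graph, _ = generate_ppi(
            module_sizes=(10, 8), n_background=0, p_in=0.9, p_out=0.0,
            n_hubs=0, n_small_components=3, seed=0,
        )
        comps = connected_components(graph)
        assert len(comps) == 2 + 3

    def test_within_module_edge_count_matches_binomial_moments(self):
        s = 30
        p_in = 0.4
        counts = []
        for seed in range(20):
            graph, truth = generate_ppi(
                module_sizes=(s, s), n_background=0, p_in=p_in, p_out=0.0,
                n_hubs=0, n_small_components=0, seed=seed,
            )
            mod1 = {g for g, m in truth.module_assignment.items() if m == "module1"}
            within = sum(1 for u, v in graph.edges() if u in mod1 and v in mod1)
            counts.append(within)
        n_pairs = s * (s - 1) / 2
        mean, sd = p_in * n_pairs, np.sqrt(n_pairs * p_in * (1 - p_in))
        assert abs(np.mean(counts) - mean) < 4 * sd / np.sqrt(len(counts))

    def test_published_module_cardinalities_supported(self):
        graph, truth = generate_ppi(module_sizes=(86, 63), n_background=50, seed=0)
        sizes = pd.Series(truth.module_assignment).value_counts()
        assert sizes["module1"] == 86
        assert sizes["module2"] == 63

    def test_graph_is_simple(self):
        graph, _ = generate_ppi(module_sizes=(15, 12), n_background=30, seed=2)
        for u, v in graph.edges():
            assert u != v

    def test_rejects_unidentifiable_structure(self):
        with pytest.raises(ValueError, match="p_in"):
            generate_ppi(module_sizes=(10, 10), p_in=0.1, p_out=0.2)
        with pytest.raises(ValueError, match="module sizes"):
            generate_ppi(module_sizes=(2, 10))

    def test_planted_hubs_top_degree_over_seeds(self):
        """With hub_extra_degree >= 5x mean background degree the planted
        hubs land in the top-n_hubs degrees in >= 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            graph, truth = generate_ppi(
                module_sizes=(30, 30), n_background=140, p_in=0.2, p_out=0.02,
                n_hubs=5, hub_extra_degree=40, n_small_components=0, seed=seed,
            )
            degrees = sorted(graph.nodes, key=lambda n: -graph.degree(n))
            hits += truth.hub_genes <= set(degrees[:5])
        assert hits >= 0.95 * n_seeds


class TestFixtureBundle:
    BUNDLE_KW = dict(
        n_genes=200, n_pairs=6, module_sizes=(15, 12), n_background=60,
        n_small_components=3, n_hubs=3, hub_extra_degree=15,
    )

    def test_byte_identical_across_runs(self, tmp_path):
        m1 = write_fixture_bundle(tmp_path / "a", seed=9, **self.BUNDLE_KW)
        m2 = write_fixture_bundle(tmp_path / "b", seed=9, **self.BUNDLE_KW)
        for name in m1["files"]:
            a = open(m1["files"][name]["path"], "rb").read()
            b = open(m2["files"][name]["path"], "rb").read()
            assert a == b, name

    def test_manifest_row_counts(self, tmp_path):
        m = write_fixture_bundle(tmp_path, seed=1, **self.BUNDLE_KW)
        expr = read_expression(
            tmp_path / "expression.tsv", tmp_path / "design.tsv",
            tmp_path / "probe_map.tsv",
        )
        assert m["files"]["expression"]["n_rows"] == len(expr.values)
        assert m["files"]["design"]["n_rows"] == 12
        assert m["files"]["truth"]["n_rows"] == 200

    def test_round_trip_graph_and_truth(self, tmp_path):
        m = write_fixture_bundle(tmp_path, seed=4, **self.BUNDLE_KW)
        graph = read_string_edges(tmp_path / "edges.tsv", min_combined_score=0.4)
        assert graph.n_edges == m["files"]["edges"]["n_rows"]
        assert m["n_graph_edges"] == graph.n_edges
        truth = read_truth(tmp_path / "truth.tsv")
        # bundle coherence: the planted graph's genes are the DE genes
        assert graph.nodes <= truth.de_genes
        expr = read_expression(
            tmp_path / "expression.tsv", tmp_path / "design.tsv",
            tmp_path / "probe_map.tsv",
        )
        expr.validate()
        # float round-trip is exact
        expr2 = read_expression(
            tmp_path / "expression.tsv", tmp_path / "design.tsv",
            tmp_path / "probe_map.tsv",
        )
        pd.testing.assert_frame_equal(expr.values, expr2.values)

    def test_unwritable_path_names_path(self, tmp_path):
        target = tmp_path / "file.txt"
        target.write_text("x")
        with pytest.raises(OSError, match="not writable"):
            write_fixture_bundle(target, seed=0)

    def test_type_i_error_calibration_under_null(self):
        """With de_fraction=0 the p<0.01 rate stays within binomial noise
        of the nominal level."""
        n_genes = 1500
        rates = []
        for seed in range(5):
            expr, _ = generate_expression(
                n_genes, 25, de_fraction=0.0, probes_per_gene=(1, 1), seed=seed
            )
            table = dge.moderated_paired_t(expr)
            rates.append((table["p"] < 0.01).mean())
        tol = 3 * np.sqrt(0.01 * 0.99 / n_genes)
        assert abs(np.mean(rates) - 0.01) < tol
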