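import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from commgenes import dge
from commgenes.containers import ExpressionMatrix
from commgenes.synthetic import generate_expression

from conftest import make_paired_expression


class TestModeratedPairedT:
    def test_equal_variances_reduce_to_classical_t(self):
        """When every probe has the same sample variance, shrinkage is a
        no-op and the moderated t equals the ordinary paired t."""
        rng = np.random.default_rng(1)
        base = rng.normal(0.5, 1.0, 8)
        diffs = np.stack(
            [rng.permutation(base) * rng.choice([-1.0, 1.0]) for _ in range(60)]
        )
        expr = make_paired_expression(diffs)
        table = dge.moderated_paired_t(expr)
        classical = diffs.mean(1) / np.sqrt(diffs.var(1, ddof=1) / diffs.shape[1])
        assert np.abs(table["t_mod"].to_numpy() - classical).max() < 1e-12
        assert np.isinf(table["df_total"]).all()

    def test_no_shrinkage_reproduces_classical_t_exactly(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.3, 1.0, size=(40, 10)) * rng.uniform(
            0.5, 2.0, size=(40, 1)
        )
        expr = make_paired_expression(diffs)
        table = dge.moderated_paired_t(expr, prior_df=0)
        classical = diffs.mean(1) / np.sqrt(diffs.var(1, ddof=1) / 10)
        np.testing.assert_allclose(table["t_mod"], classical, rtol=0, atol=1e-12)
        assert (table["df_total"] == 9).all()

    def test_zero_variance_probe_finite_t_under_shrinkage(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.0, 1.0, size=(30, 10))
        diffs[0] = 1.0  # constant differences: s^2 = 0, logFC = 1
        expr = make_paired_expression(diffs)
        table = dge.moderated_paired_t(expr)
        row = table.iloc[0]
        assert row["logFC"] == pytest.approx(1.0)
        assert np.isfinite(row["t_mod"])
        assert row["t_mod"] == table["t_mod"].abs().max()

    def test_all_zero_variance_rejected(self):
        # constant integer-valued samples: differences are exactly constant
        probes = [f"pr{i}" for i in range(10)]
        samples = [f"P{j}_{c}" for j in range(5) for c in ("NL", "LL")]
        values = pd.DataFrame(
            [[8.0, 9.0] * 5] * 10, index=probes, columns=samples
        )
        design = pd.DataFrame(
            {"patient": [s.split("_")[0] for s in samples],
             "condition": [s.split("_")[1] for s in samples]},
            index=pd.Index(samples, name="sample"),
        )
        expr = ExpressionMatrix(values, design, pd.Series(probes, index=probes))
        with pytest.raises(ValueError, match="zero variance"):
            dge.moderated_paired_t(expr)

    def test_unpaired_sample_names_patient(self):
        rng = np.random.default_rng(0)
        expr = make_paired_expression(rng.normal(size=(5, 4)))
        design = expr.design.copy()
        design.loc["P002_LL", "condition"] = "NL"
        expr.design = design
        with pytest.raises(ValueError, match="P002"):
            dge.moderated_paired_t(expr)

    def test_shrinkage_pulls_extreme_variances_together(self):
        """Posterior variances lie between each probe's sample variance and
        the common prior scale."""
        rng = np.random.default_rng(5)
        sds = rng.uniform(0.2, 3.0, size=200)
        diffs = rng.normal(0, 1, size=(200, 6)) * sds[:, None]
        expr = make_paired_expression(diffs)
        table = dge.moderated_paired_t(expr)
        classical = diffs.mean(1) / np.sqrt(diffs.var(1, ddof=1) / 6)
        # moderated |t| should be damped for tiny-variance probes: the
        # spread of moderated t is no larger than classical
        assert np.std(table["t_mod"]) <= np.std(classical) + 1e-9

    def test_logfc_recovery_correlates_with_truth(self):
        expr, truth = generate_expression(
            600, 30, de_fraction=0.5, effect_range=(2.0, 2.0), noise_sd=0.5, seed=11
        )
        table = dge.moderated_paired_t(expr)
        genes = dge.collapse_probes(table, expr.probe_map)
        true_fc = pd.Series(truth.effect_sizes).loc[genes.index]
        r = np.corrcoef(genes["logFC"], true_fc)[0, 1]
        assert r >= 0.95


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            dge.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert dge.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(dge.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500) ** 2
        ours = dge.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(dge.bh_adjust(p)[perm], dge.bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dge.bh_adjust([0.5, 1.2])


class TestSelectDegs:
    @staticmethod
    def table(rows):
        return pd.DataFrame(
            rows, columns=["logFC", "p", "fdr"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_boundary_conventions(self):
        # |logFC| >= 1 inclusive; p and fdr strict
        t = self.table([
            (0.9, 1e-6, 1e-5),     # excluded: |logFC| < 1
            (-1.0, 0.005, 0.009),  # included: inclusive logFC boundary
            (2.0, 0.01, 0.001),    # excluded: p not < 0.01
            (2.0, 0.001, 0.01),    # excluded: fdr not < 0.01
        ])
        kept = dge.select_degs(t)
        assert list(kept.index) == ["g1"]

    def test_top_n_truncation(self):
        rng = np.random.default_rng(1)
        n = 3000
        t = pd.DataFrame(
            {
                "logFC": rng.uniform(1, 4, n) * rng.choice([-1, 1], n),
                "p": rng.uniform(0, 0.005, n),
                "fdr": rng.uniform(0, 0.005, n),
            },
            index=[f"g{i:05d}" for i in range(n)],
        )
        kept = dge.select_degs(t, top_n=2000)
        assert len(kept) == 2000
        # ranking rule: ascending fdr
        assert kept["fdr"].is_monotonic_increasing

    def test_requires_columns(self):
        with pytest.raises(ValueError, match="fdr"):
            dge.select_degs(pd.DataFrame({"logFC": [1.0], "p": [0.001]}))


class TestCollapseProbes:
    @staticmethod
    def table(index, logfc):
        return pd.DataFrame(
            {"logFC": logfc, "t_mod": logfc, "p": 0.001, "fdr": 0.002},
            index=index,
        )

    def test_max_absolute_rule_keeps_sign(self):
        t = self.table(["p1", "p2"], [1.2, -2.5])
        out = dge.collapse_probes(t, {"p1": "X", "p2": "X"})
        assert out.loc["X", "logFC"] == -2.5

    def test_one_probe_per_gene_identity(self):
        t = self.table(["p1", "p2"], [1.0, -1.5])
        out = dge.collapse_probes(t, {"p1": "A", "p2": "B"})
        assert out.loc["A", "logFC"] == 1.0
        assert out.loc["B", "logFC"] == -1.5

    def test_tie_breaks_to_smallest_probe_id(self):
        t = self.table(["pB", "pA"], [2.0, -2.0])
        out = dge.collapse_probes(t, {"pA": "X", "pB": "X"})
        assert out.loc["X", "logFC"] == -2.0  # pA wins lexicographically

    def test_idempotent_on_gene_keyed_tables(self):
        t = self.table(["GENE1", "GENE2"], [1.0, 2.0])
        once = dge.collapse_probes(t, {"GENE1": "GENE1", "GENE2": "GENE2"})
        twice = dge.collapse_probes(once, {"GENE1": "GENE1", "GENE2": "GENE2"})
        pd.testing.assert_frame_equal(once, twice)

    def test_unmapped_probe_listed(self):
        t = self.table(["p1", "p2"], [1.0, 2.0])
        with pytest.raises(KeyError, match="p2"):
            dge.collapse_probes(t, {"p1": "X"})
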