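import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from immunoqtl import DosageMatrix, UsageMatrix, bh_fdr, fit_pair, qq_lambda, scan
from immunoqtl.association import CHI2_MEDIAN_1DF


class TestFitPair:
    def test_closed_form_worked_example(self):
        beta, se, t, p = fit_pair([1, 2, 3, 4], [0, 1, 1, 2])
        assert beta == pytest.approx(1.5)
        assert se == pytest.approx(0.35355339, abs=1e-7)
        assert t == pytest.approx(4.2426407, abs=1e-6)
        assert p == pytest.approx(0.05131670, abs=1e-7)

    def test_perfect_fit_reports_smallest_p(self):
        d = np.array([0, 1, 1, 2, 0, 2])
        beta, se, t, p = fit_pair(2.0 * d, d)
        assert beta == pytest.approx(2.0)
        assert p == np.finfo(float).tiny

    def test_zero_variance_dosage_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pair([1.0, 2.0, 3.0], [1, 1, 1])

    def test_null_beta_near_zero_large_n(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=5000).astype(float)
        y = rng.normal(size=5000)
        beta, se, t, p = fit_pair(y, d)
        assert abs(beta) < 3 * se * 2


class TestScan:
    def _random_instance(self, rng, n):
        n_var, n_gene = int(rng.integers(1, 5)), int(rng.integers(1, 4))
        D = rng.integers(0, 3, size=(n, n_var))
        while (D.std(axis=0) == 0).any():
            D = rng.integers(0, 3, size=(n, n_var))
        Y = rng.normal(size=(n, n_gene))
        idx = pd.Index([f"i{k}" for k in range(n)], name="individual_id")
        dm = DosageMatrix(pd.DataFrame(
            D.astype(np.int8), index=idx,
            columns=[f"HLA-A.amino_acid.{j + 1}.A" for j in range(n_var)],
        ))
        pheno = pd.DataFrame(Y, index=idx, columns=[f"TRBV{g + 1}" for g in range(n_gene)])
        return dm, pheno

    def test_agrees_with_statsmodels_ols_per_pair(self):
        """Independent oracle: per-pair OLS via statsmodels on random instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            dm, pheno = self._random_instance(rng, n)
            table = scan(pheno, dm).set_index(["variant_id", "gene_id"])
            for vid in dm.values.columns:
                for gene in pheno.columns:
                    fit = sm.OLS(pheno[gene].to_numpy(),
                                 sm.add_constant(dm.values[vid].to_numpy(float))).fit()
                    row = table.loc[(vid, gene)]
                    assert row["beta"] == pytest.approx(fit.params[1], abs=1e-10)
                    assert row["se"] == pytest.approx(fit.bse[1], abs=1e-10)
                    assert row["p_value"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_single_pair_reduces_to_fit_pair(self):
        idx = pd.Index(["a", "b", "c", "d"], name="individual_id")
        dm = DosageMatrix(pd.DataFrame({"HLA-A.amino_acid.1.A": [0, 1, 1, 2]}, index=idx))
        pheno = pd.DataFrame({"TRBV1": [1.0, 2.0, 3.0, 4.0]}, index=idx)
        table = scan(pheno, dm)
        assert len(table) == 1
        beta, se, t, p = fit_pair([1, 2, 3, 4], [0, 1, 1, 2])
        assert table.loc[0, "beta"] == pytest.approx(beta)
        assert table.loc[0, "p_value"] == pytest.approx(p)
        assert table.loc[0, "q_value"] == pytest.approx(p)

    def test_zero_variance_columns_skipped_and_row_count(self):
        rng = np.random.default_rng(3)
        idx = pd.Index([f"i{k}" for k in range(30)], name="individual_id")
        values = pd.DataFrame(
            {
                "HLA-A.amino_acid.1.A": rng.integers(0, 3, 30).astype(np.int8),
                "HLA-A.amino_acid.2.A": np.ones(30, dtype=np.int8),  # constant
                "HLA-A.amino_acid.3.A": rng.integers(0, 3, 30).astype(np.int8),
            },
            index=idx,
        )
        dm = DosageMatrix(values)
        pheno = pd.DataFrame(rng.normal(size=(30, 4)), index=idx,
                             columns=[f"TRBV{g}" for g in range(4)])
        table = scan(pheno, dm)
        assert len(table) == 2 * 4  # variants with variance x genes
        assert "HLA-A.amino_acid.2.A" not in set(table["variant_id"])

    def test_disjoint_individuals_error(self):
        dm = DosageMatrix(pd.DataFrame({"HLA-A.amino_acid.1.A": [0, 1, 2]},
                                       index=pd.Index(["a", "b", "c"], name="individual_id")))
        pheno = pd.DataFrame({"TRBV1": [0.1, 0.2, 0.3]},
                             index=pd.Index(["x", "y", "z"], name="individual_id"))
        with pytest.raises(ValueError, match="shared"):
            scan(pheno, dm)

    def test_planted_effect_attains_minimum_p(self, cohort_200):
        _, genotypes, _, aa = cohort_200
        from immunoqtl import EffectSpec, SimulationConfig, generate_usage

        vid = aa.values.columns[5]
        usage, _ = generate_usage(
            genotypes, aa, EffectSpec([(vid, "TRBV1", 1.0)]),
            SimulationConfig(n_individuals=200, noise_sd=0.05, dropout_rate=0.0, seed=9),
        )
        table = scan(usage, aa)
        planted_row = table[(table["variant_id"] == vid) & (table["gene_id"] == "TRBV1")]
        # the planted pair attains the table's minimum p (ties with perfect proxies allowed)
        assert planted_row["p_value"].iloc[0] == table["p_value"].min()
        top = table.sort_values("p_value").iloc[0]
        assert top["gene_id"] == "TRBV1"


class TestBhFdr:
    def test_step_up_worked_example(self):
        q, flags = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_single_p_identity_and_identical_ps(self):
        q, _ = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        q, _ = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_empty_input(self):
        q, flags = bh_fdr([])
        assert len(q) == 0 and len(flags) == 0

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_order_invariance_and_q_bounds(self, ps):
        q, _ = bh_fdr(ps)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        q_perm, _ = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(q[perm], q_perm)
        assert (q >= np.asarray(ps) - 1e-15).all() and (q <= 1.0).all()


class TestQqLambda:
    def test_lambda_exactly_one_when_all_half(self):
        rep = qq_lambda(np.full(100, 0.5))
        assert rep.lambda_gc == pytest.approx(1.0)

    def test_uniform_null_calibration(self):
        rng = np.random.default_rng(1)
        rep = qq_lambda(rng.uniform(size=10_000))
        assert 0.95 <= rep.lambda_gc <= 1.05
        assert rep.n_tests == 10_000
        assert len(rep.qq) == 10_000

    def test_strong_signal_matches_chi_square_quantile(self):
        from scipy import stats

        rep = qq_lambda(np.full(50, 0.001))
        expected = stats.chi2.isf(0.001, 1) / CHI2_MEDIAN_1DF
        assert rep.lambda_gc == pytest.approx(expected)
        assert rep.lambda_gc == pytest.approx(23.8, abs=0.5)

    def test_zero_p_clamped(self):
        rep = qq_lambda([0.0, 0.5, 0.5])
        assert np.isfinite(rep.lambda_gc)
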