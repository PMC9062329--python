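"""Cis-eQTL scan: covariates, OLS, permutations, FDR, leading SNPs, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

import eqtl_design as ed
from eqtl_design.errors import ParameterError
from eqtl_design.mapping import _principal_components


class TestCovariates:
    def _toy(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        panel = ed.simulate_gene_panel(6, seed=seed)
        geno = ed.simulate_genotypes(n, 3, panel, seed=seed)
        tpm = ed.ExpressionMatrix(
            rng.uniform(0, 100, (6, n)),
            panel.gene_id,
            geno.sample_id,
            unit="tpm",
        )
        return geno, tpm

    def test_zero_pcs_is_intercept_only(self):
        geno, tpm = self._toy()
        c = ed.compute_covariates(geno, tpm, 0, 0)
        assert c.shape == (12, 1)
        assert np.all(c == 1.0)

    def test_pcs_match_eigendecomposition(self):
        # eigen oracle: PC variances equal eigenvalues of the covariance
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        pcs = _principal_components(x, 3)
        xc = x - x.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        assert np.allclose(np.sort((pcs**2).sum(axis=0))[::-1], eigvals, atol=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 4))
        a = _principal_components(x, 2)
        b = _principal_components(x.copy(), 2)
        assert np.array_equal(a, b)

    def test_too_many_pcs_rejected(self):
        geno, tpm = self._toy()
        with pytest.raises(ParameterError):
            ed.compute_covariates(geno, tpm, 6, 6)


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        r = ed.residualize(y, np.ones((4, 1)))
        assert np.allclose(r, y - y.mean())

    def test_phenotype_in_covariate_span_gives_zero(self):
        c = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 3.0 + 2.0 * np.arange(5.0)
        assert np.allclose(ed.residualize(y, c), 0.0, atol=1e-10)

    def test_matches_normal_equations_and_orthogonality(self):
        rng = np.random.default_rng(7)
        c = np.column_stack([np.ones(5), rng.normal(size=(5, 2))])
        y = rng.normal(size=5)
        beta = np.linalg.solve(c.T @ c, c.T @ y)
        assert np.allclose(ed.residualize(y, c), y - c @ beta, atol=1e-10)
        assert np.max(np.abs(c.T @ ed.residualize(y, c))) < 1e-8

    def test_collinear_columns_dropped(self):
        c = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        y = np.arange(6.0) ** 2
        r = ed.residualize(y, c)
        assert np.max(np.abs(c[:, :2].T @ r)) < 1e-8


class TestNominalScan:
    def test_hand_ols_example(self):
        # normal-equations oracle: beta = 2.92/2.8 = 1.0429
        rec = ed.nominal_scan(
            np.array([0.1, 0.9, 2.1, 1.1, -0.1]),
            np.array([0, 1, 2, 1, 0])[:, None],
            np.array(["snp1"]),
            np.array([100]),
            tss=50,
        )
        assert rec["beta"].iloc[0] == pytest.approx(1.0429, abs=1e-3)
        assert rec["distance_to_tss"].iloc[0] == 50

    def test_perfect_fit_flagged_with_floored_p(self):
        g = np.array([0, 1, 2, 1, 0])
        rec = ed.nominal_scan(2.0 * g, g[:, None], np.array(["s"]), np.array([1]), tss=1)
        assert rec["perfect_fit"].iloc[0]
        assert rec["beta"].iloc[0] == pytest.approx(2.0)
        assert rec["nominal_p"].iloc[0] > 0

    def test_monomorphic_snps_dropped(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.column_stack([np.ones(4), [0, 1, 2, 1]])
        rec = ed.nominal_scan(y, g, np.array(["mono", "poly"]), np.array([5, 6]), tss=0)
        assert list(rec["snp_id"]) == ["poly"]

    def test_null_p_values_uniform(self):
        # uniformity oracle: KS test across many independent null genes
        rng = np.random.default_rng(15)
        pvals = []
        for _ in range(1000):
            y = rng.normal(size=50)
            g = rng.binomial(2, 0.3, size=50).astype(float)
            if g.std() == 0:
                continue
            rec = ed.nominal_scan(y, g[:, None], np.array(["s"]), np.array([1]), tss=0)
            pvals.append(rec["nominal_p"].iloc[0])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLeadingSnp:
    def _records(self):
        return pd.DataFrame(
            {
                "gene_id": ["g"] * 3,
                "snp_id": ["c", "a", "b"],
                "beta": [1.0, 0.9, 0.8],
                "se": [0.1] * 3,
                "nominal_p": [1e-8, 1e-8, 1e-3],
                "distance_to_tss": [-500, 200, 100],
                "perfect_fit": [False] * 3,
            }
        )

    def test_single_snp(self):
        rec = self._records().iloc[[2]]
        assert ed.select_leading_snp(rec)["snp_id"] == "b"

    def test_tie_broken_by_distance(self):
        assert ed.select_leading_snp(self._records())["snp_id"] == "a"

    def test_order_invariance(self):
        rec = self._records()
        for perm in itertools.permutations(range(3)):
            shuffled = rec.iloc[list(perm)].reset_index(drop=True)
            assert ed.select_leading_snp(shuffled)["snp_id"] == "a"


class TestPermutationPass:
    def test_extreme_observed_statistic(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, size=200).astype(float)
        y = 2.0 * g + rng.normal(0, 0.01, 200)
        res = ed.permutation_pass(y, g[:, None], n_perm=1000, seed=1)
        assert res.perm_p == pytest.approx(1.0 / 1001.0)

    def test_matches_exhaustive_enumeration(self):
        # exhaustive oracle at n=5: all 120 permutations of y
        rng = np.random.default_rng(2)
        y = np.array([0.3, -1.2, 0.7, 1.9, -0.5])
        g = np.array([[0, 1], [1, 0], [2, 1], [1, 2], [0, 0]], dtype=float)

        def stat(yv):
            yc = yv - yv.mean()
            gc = g - g.mean(axis=0)
            r = (gc * yc[:, None]).sum(axis=0) / np.sqrt(
                (gc**2).sum(axis=0) * (yc**2).sum()
            )
            return np.abs(r).max()

        obs = stat(y)
        exact = np.array([stat(y[list(p)]) for p in itertools.permutations(range(5))])
        p_exact = (exact >= obs - 1e-12).mean()
        n_perm = 10_000
        res = ed.permutation_pass(y, g, n_perm=n_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.perm_p - p_exact) < 3 * se + 2.0 / n_perm

    def test_null_perm_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for k in range(200):
            y = rng.normal(size=40)
            g = rng.binomial(2, 0.3, size=(40, 3)).astype(float)
            res = ed.permutation_pass(y, g, n_perm=200, seed=k)
            ps.append(res.perm_p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.005

    def test_beta_approximation_tracks_empirical_p(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=60)
        g = rng.binomial(2, 0.25, size=(60, 5)).astype(float)
        res = ed.permutation_pass(y, g, n_perm=2000, seed=6, beta_approx=True)
        assert res.beta_approx_p == pytest.approx(res.perm_p, abs=0.1)

    def test_no_polymorphic_snp_skipped(self):
        y = np.arange(10.0)
        assert ed.permutation_pass(y, np.ones((10, 2)), n_perm=100, seed=0) is None


class TestFdr:
    def test_all_p_one_no_egenes(self):
        q, flags = ed.fdr_correct(np.ones(10), method="qvalue")
        assert not flags.any()

    def test_bh_step_up_oracle(self):
        # step-up by hand: p_(2)=0.008 <= 2*0.05/5 but p_(3)=0.039 > 0.03,
        # so exactly the two smallest are rejected (statsmodels agrees)
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.9])
        q, flags = ed.fdr_correct(p, method="bh", level=0.05)
        assert list(flags) == [True, True, False, False, False]
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_qvalue_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1, 50)
        q_bh, _ = ed.fdr_correct(p, method="bh")
        q_st, _ = ed.fdr_correct(p, method="qvalue", pi0=1.0)
        assert np.allclose(q_bh, q_st)

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.0001, 1, 200)
        q, _ = ed.fdr_correct(p, method="qvalue")
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            ed.fdr_correct(np.array([0.0, 0.5]))

    def test_empty_input(self):
        q, flags = ed.fdr_correct(np.array([]))
        assert q.size == 0 and flags.size == 0


class TestDriver:
    def test_leading_snp_recovers_causal(self, cohort):
        # with beta=0.5 at n=150 the causal SNP should lead or be in strong
        # LD for nearly all detected eGenes
        res = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=500, seed=3
        )
        assert res.n_egenes > 20
        truth = dict(zip(cohort.truth.gene_id, cohort.truth.causal_snp_id))
        tab = res.table[res.table["is_egene"]]
        ok = 0
        total = 0
        for row in tab.itertuples():
            causal = truth[row.gene_id]
            if causal is None:
                continue
            total += 1
            if row.snp_id == causal:
                ok += 1
            else:
                a = cohort.genotypes.dosages[:, cohort.genotypes.index_of(causal)].astype(float)
                b = cohort.genotypes.dosages[:, cohort.genotypes.index_of(row.snp_id)].astype(float)
                if np.corrcoef(a, b)[0, 1] ** 2 > 0.8:
                    ok += 1
        assert total > 0 and ok / total >= 0.9

    def test_power_monotone_in_coverage(self, cohort):
        from tests_support import scaled_grid

        counts = []
        for cov in scaled_grid(cohort.panel.n_genes, (5.0, 50.0)):
            thin = ed.downsample_counts(
                cohort.counts, cov, n_replicates=1, seed=7, allow_partial=True
            )[0]
            res = ed.map_cis_eqtls(
                cohort.panel, cohort.genotypes, counts=thin, n_perm=300, seed=3
            )
            counts.append(res.n_egenes)
        assert counts[0] <= counts[1]

    def test_determinism(self, cohort):
        a = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=200, seed=5
        )
        b = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=200, seed=5
        )
        pd.testing.assert_frame_equal(a.table, b.table)


class TestConcordance:
    def test_self_comparison_is_perfect(self, cohort):
        res = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=300, seed=3
        )
        m = ed.concordance(res, res, cohort.genotypes)
        assert m["effect_r2"] == pytest.approx(1.0)
        assert m["neglog_p_slope"] == pytest.approx(1.0)
        assert m["mean_leading_ld_r2"] == pytest.approx(1.0)
        assert m["shared_leading_esnp"] == m["shared_egenes"]

    def test_sign_flip_leaves_effect_r2(self, cohort):
        res = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=300, seed=3
        )
        flipped = ed.EGeneTable(res.table.assign(beta=-res.table["beta"]), res.fdr_level)
        m = ed.concordance(res, flipped, cohort.genotypes)
        assert m["effect_r2"] == pytest.approx(1.0)

    def test_low_coverage_slope_below_one(self, cohort):
        # power-attenuation direction: the noisier dataset's -log10 p
        # regress on the cleaner one's with slope < 1
        from tests_support import scaled_grid

        full = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=cohort.counts, n_perm=300, seed=3
        )
        low_cov = scaled_grid(cohort.panel.n_genes, (5.0,))[0]
        thin = ed.downsample_counts(
            cohort.counts, low_cov, n_replicates=1, seed=9, allow_partial=True
        )[0]
        low = ed.map_cis_eqtls(
            cohort.panel, cohort.genotypes, counts=thin, n_perm=300, seed=3
        )
        m = ed.concordance(full, low, cohort.genotypes)
        assert m["shared_egenes"] > 5
        assert m["neglog_p_slope"] < 1.0
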