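"""Kinship, REML null model, score scan, genomic control, variance explained."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cnvqtl import (
    GenotypeMatrix,
    conditional_scan,
    fit_null,
    genomic_lambda,
    kinship,
    score_scan,
    simulate_phenotypes,
    simulate_population,
    variance_explained,
)
from cnvqtl.mixedmodel import KinshipMatrix, bonferroni_threshold

COVS = ("sex", "batch", "carcass_weight")


def brute_force_score(y, X, V, x):
    """Score statistic via explicit projected-inverse-covariance matrices.

    Builds P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 with dense inverses and
    returns (beta, chi2). Independent of the eigenbasis fast path.
    """
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
    u = x @ P @ y
    d = x @ P @ x
    return u / d, u ** 2 / d


def _toy_geno(n=50, m=8, seed=0):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, m)).astype(float)
    dosage[0] = 1.0  # keep every SNP polymorphic
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)],
        np.array(["1"] * m, dtype=object),
        np.arange(1, m + 1) * 1000, dosage)


def _toy_pheno(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "ear_area": rng.normal(130, 10, n),
        "sex": rng.integers(0, 2, n),
        "batch": rng.integers(1, 4, n),
        "carcass_weight": rng.normal(90, 8, n),
    })


class TestKinship:
    def test_identical_rows_have_raw_ibs_one(self):
        g = _toy_geno(4, 6)
        g.dosage[1] = g.dosage[0]
        K = kinship(g, weighting="raw")
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_have_raw_ibs_zero(self):
        dosage = np.array([[0.0] * 5, [2.0] * 5, [1.0] * 5])
        g = GenotypeMatrix(["a", "b", "c"], [f"v{j}" for j in range(5)],
                           np.array(["1"] * 5, dtype=object),
                           np.arange(1, 6) * 10, dosage)
        K = kinship(g, weighting="raw")
        assert K.values[0, 1] == pytest.approx(0.0)
        assert K.values[0, 2] == pytest.approx(0.5)

    def test_raw_ibs_matches_per_pair_loop(self):
        g = _toy_geno(5, 12, seed=3)
        g.dosage[2, 4] = np.nan  # exercise pairwise deletion
        K = kinship(g, weighting="raw")
        for i in range(5):
            for j in range(5):
                a, b = g.dosage[i], g.dosage[j]
                ok = ~(np.isnan(a) | np.isnan(b))
                expected = np.mean(1.0 - np.abs(a[ok] - b[ok]) / 2.0)
                assert K.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_no_overlap_pair_raises_with_names(self):
        dosage = np.array([[0.0, np.nan], [np.nan, 1.0], [1.0, 1.0]])
        g = GenotypeMatrix(["a", "b", "c"], ["v0", "v1"],
                           np.array(["1", "1"], dtype=object),
                           np.array([10, 20]), dosage)
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            kinship(g, weighting="raw")


class TestFitNull:
    def test_identity_kinship_recovers_ols_residual_variance(self):
        pheno = _toy_pheno(200, seed=1)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(200))
        fit = fit_null(pheno, COVS, kin)
        X = fit.X
        ols = sm.OLS(pheno["ear_area"].to_numpy(), X).fit()
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(ols.mse_resid, rel=1e-6)

    def test_heritability_recovery(self):
        """Pure polygenic phenotype at h2=0.5 estimated within [0.3, 0.7]."""
        geno, truth = simulate_population(500, 400, block_size=5, seed=21,
                                          effect_per_copy=0.0,
                                          polygenic_h2=0.5,
                                          covariate_effects={})
        pheno = simulate_phenotypes(geno, truth)
        kin = kinship(geno)
        fit = fit_null(pheno, COVS, kin)
        assert 0.3 <= fit.heritability <= 0.7

    def test_zero_variance_phenotype_raises(self):
        pheno = _toy_pheno(30)
        pheno["ear_area"] = 5.0
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(30))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_null(pheno, COVS, kin)

    def test_nonfinite_phenotype_raises(self):
        pheno = _toy_pheno(30)
        pheno.loc[0, "ear_area"] = np.nan
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(30))
        with pytest.raises(ValueError, match="non-finite"):
            fit_null(pheno, COVS, kin)


class TestScoreScan:
    def test_matches_brute_force_oracle_with_identity_kinship(self):
        geno = _toy_geno(50, 8, seed=5)
        pheno = _toy_pheno(50, seed=6)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(50))
        fit = fit_null(pheno, COVS, kin)
        results = score_scan(geno, fit)
        V = (fit.sigma_g2 + fit.sigma_e2) * np.eye(50)
        y = pheno["ear_area"].to_numpy()
        for j, r in enumerate(results):
            beta, chi2 = brute_force_score(y, fit.X, V, geno.dosage[:, j])
            assert r.beta == pytest.approx(beta, rel=1e-6)
            assert r.chi2 == pytest.approx(chi2, rel=1e-6)

    def test_matches_brute_force_oracle_with_structured_kinship(self):
        geno, truth = simulate_population(60, 40, block_size=4, seed=22)
        pheno = simulate_phenotypes(geno, truth)
        kin = kinship(geno)
        fit = fit_null(pheno, COVS, kin)
        results = score_scan(geno, fit)
        # rebuild the fitted covariance from the eigen decomposition
        U, s = fit.eig_vectors, fit.eig_values
        V = U @ np.diag(fit.sigma_g2 * s + fit.sigma_e2) @ U.T
        y = pheno["ear_area"].to_numpy()
        for j in (0, 7, 20, 39):
            beta, chi2 = brute_force_score(y, fit.X, V, geno.dosage[:, j])
            assert results[j].beta == pytest.approx(beta, rel=1e-6)
            assert results[j].chi2 == pytest.approx(chi2, rel=1e-6)

    def test_beta_equals_ols_when_no_polygenic_term(self):
        geno = _toy_geno(50, 8, seed=5)
        pheno = _toy_pheno(50, seed=6)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(50))
        fit = fit_null(pheno, COVS, kin)
        y = pheno["ear_area"].to_numpy()
        for j, r in enumerate(score_scan(geno, fit)):
            X = np.column_stack([fit.X, geno.dosage[:, j]])
            ols = sm.OLS(y, X).fit()
            assert r.beta == pytest.approx(float(ols.params[-1]), rel=1e-8)

    def test_perfect_signal(self):
        """y exactly equal to dosage: beta 1 and chi2 at the score-test cap.

        A score test evaluates the variance under the null fit, so its chi2
        saturates near n for a perfect fit rather than diverging; the P-value
        is the smallest the statistic can reach at this sample size.
        """
        geno = _toy_geno(60, 3, seed=7)
        pheno = _toy_pheno(60, seed=8)
        pheno["ear_area"] = geno.dosage[:, 1] + 1e-9 * np.arange(60)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(60))
        fit = fit_null(pheno, ("carcass_weight",), kin)
        r = score_scan(geno, fit)[1]
        assert r.beta == pytest.approx(1.0, abs=1e-6)
        assert r.chi2 == pytest.approx(58.0, abs=0.1)  # n minus fixed effects
        assert r.lod > 12

    def test_monomorphic_snp_flagged(self):
        geno = _toy_geno(40, 3, seed=9)
        geno.dosage[:, 2] = 1.0
        pheno = _toy_pheno(40, seed=9)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(40))
        fit = fit_null(pheno, COVS, kin)
        r = score_scan(geno, fit)[2]
        assert r.flag == "monomorphic"
        assert r.p == 1.0

    def test_chi2_invariant_to_affine_phenotype_rescaling(self):
        geno = _toy_geno(80, 5, seed=10)
        pheno = _toy_pheno(80, seed=11)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(80))
        chi_a = [r.chi2 for r in score_scan(geno, fit_null(pheno, COVS, kin))]
        pheno2 = pheno.copy()
        pheno2["ear_area"] = 3.5 * pheno["ear_area"] - 40.0
        chi_b = [r.chi2 for r in score_scan(geno, fit_null(pheno2, COVS, kin))]
        np.testing.assert_allclose(chi_a, chi_b, rtol=1e-8)

    def test_lod_is_minus_log10_p(self):
        geno = _toy_geno(50, 5, seed=12)
        pheno = _toy_pheno(50, seed=13)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(50))
        for r in score_scan(geno, fit_null(pheno, COVS, kin)):
            assert r.lod == pytest.approx(-np.log10(r.p), rel=1e-12)


class TestConditionalScan:
    def test_condition_on_causal_removes_linked_signals(self, small_population,
                                                        small_phenotypes):
        geno, truth = small_population
        kin = kinship(geno)
        fit = fit_null(small_phenotypes, COVS, kin)
        unc = score_scan(geno, fit)
        cond = conditional_scan(
            geno, fit, truth.causal_copies_per_sample.astype(float)[:, None])
        from cnvqtl import ld_r2

        copies = truth.causal_copies_per_sample.astype(float)
        linked = [j for j in range(geno.n_snps)
                  if ld_r2(geno.dosage[:, j], copies) > 0.5]
        assert linked
        gw_chi2 = stats.chi2.isf(0.05 / geno.n_snps, df=1)
        assert max(unc[j].chi2 for j in linked) > gw_chi2
        assert all(cond[j].chi2 < gw_chi2 for j in linked)
        for j in linked:
            assert cond[j].chi2 < unc[j].chi2 or cond[j].flag

    def test_condition_on_orthogonal_covariate_changes_nothing(self):
        """Conditioning on a vector orthogonal to design and dosages is a
        no-op on every statistic (and matches the brute-force oracle)."""
        geno = _toy_geno(100, 6, seed=14)
        pheno = _toy_pheno(100, seed=15)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(100))
        fit = fit_null(pheno, COVS, kin)
        rng = np.random.default_rng(16)
        raw = rng.normal(size=100)
        span = np.column_stack([fit.X, geno.dosage])
        indep = raw - span @ np.linalg.lstsq(span, raw, rcond=None)[0]
        unc = score_scan(geno, fit)
        cond = conditional_scan(geno, fit, indep[:, None])
        V = (fit.sigma_g2 + fit.sigma_e2) * np.eye(100)
        X_aug = np.column_stack([fit.X, indep])
        y = pheno["ear_area"].to_numpy()
        for j, r in enumerate(cond):
            _, chi2 = brute_force_score(y, X_aug, V, geno.dosage[:, j])
            assert r.chi2 == pytest.approx(chi2, rel=1e-8)
        np.testing.assert_allclose([r.chi2 for r in unc],
                                   [r.chi2 for r in cond], rtol=1e-8)

    def test_snp_collinear_with_conditioning_flagged(self):
        geno = _toy_geno(50, 4, seed=17)
        pheno = _toy_pheno(50, seed=18)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(50))
        fit = fit_null(pheno, COVS, kin)
        cond = conditional_scan(geno, fit, geno.dosage[:, [2]])
        assert cond[2].flag == "collinear"

    def test_conditioning_collinear_with_covariates_raises(self):
        pheno = _toy_pheno(50, seed=19)
        geno = _toy_geno(50, 3, seed=19)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(50))
        fit = fit_null(pheno, COVS, kin)
        with pytest.raises(ValueError, match="collinear"):
            conditional_scan(geno, fit, np.ones((50, 1)))


class TestScanStatistics:
    def test_genomic_lambda_calibrated_on_chi2_draws(self):
        rng = np.random.default_rng(20)
        lam = genomic_lambda(rng.chisquare(1, size=10_000))
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_variance_explained_arithmetic(self):
        # V_reduce=10, V_full=8 -> 0.2, checked through a constructed design
        rng = np.random.default_rng(21)
        n = 2000
        term = rng.normal(size=n)
        y = term * np.sqrt(2.0) + rng.normal(size=n) * np.sqrt(8.0)
        ve = variance_explained(y, None, term)
        assert ve == pytest.approx(0.2, abs=0.03)

    def test_variance_explained_null_term(self):
        rng = np.random.default_rng(22)
        y = rng.normal(size=1000)
        term = rng.normal(size=1000)
        assert abs(variance_explained(y, None, term)) < 0.01

    def test_variance_explained_zero_reduced_variance_raises(self):
        y = np.ones(10)
        with pytest.raises(ValueError):
            variance_explained(y, None, np.arange(10.0))

    def test_bonferroni(self):
        assert bonferroni_threshold(0.05, 50_000) == pytest.approx(1e-6)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_effect_recovery_across_replicates(self):
        """Per-copy effect of 15 cm^2 at n=400 recovered without bias.

        The mean of the per-replicate mixed-model estimates must lie within
        two empirical standard errors of the simulated effect.
        """
        estimates = []
        for seed in range(40):
            geno, truth = simulate_population(400, 60, block_size=6, seed=seed)
            pheno = simulate_phenotypes(geno, truth)
            kin = kinship(geno)
            fit = fit_null(pheno, COVS, kin)
            from cnvqtl.mixedmodel import _score_statistics

            x = truth.causal_copies_per_sample.astype(float)
            xPy, xPx = _score_statistics(fit, x[:, None], fit.X)
            estimates.append(xPy[0] / xPx[0])
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 15.0) <= 2 * se + 1e-9
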