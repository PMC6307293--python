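"""CNV association, interaction F-test, concordance, expression eQTL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvqtl import (
    adjust_expression,
    cnv_association,
    concordance,
    eqtl_scan,
    interaction_test,
    kinship,
    ld_r2,
    simulate_expression,
    simulate_phenotypes,
    simulate_population,
)


def _pheno_with_copies(n=400, effect=15.0, seed=0):
    rng = np.random.default_rng(seed)
    copies = rng.choice([2, 3, 4], size=n, p=[0.49, 0.42, 0.09])
    pheno = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": rng.integers(0, 2, n),
        "batch": rng.integers(1, 5, n),
        "carcass_weight": rng.normal(90, 8, n),
    })
    pheno["ear_area"] = (130.0 + 12.0 * pheno["sex"] + 4.0 * pheno["batch"]
                         + 0.6 * pheno["carcass_weight"]
                         + effect * (copies - 2)
                         + rng.normal(0, 10, n))
    return pheno, copies.astype(float)


class TestCnvAssociation:
    def test_recovers_per_copy_effect(self):
        """Per-copy effect of 15 cm^2 at n=400: unbiased over replicates
        and individually highly significant."""
        betas = []
        for seed in range(30):
            pheno, copies = _pheno_with_copies(effect=15.0, seed=seed)
            r = cnv_association(pheno, copies)
            assert r.p < 1e-6
            assert r.variance_explained > 0.1
            betas.append(r.beta)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - 15.0) <= 2.5 * se

    def test_scale_equivariance(self):
        pheno, copies = _pheno_with_copies(effect=15.0, seed=1)
        r1 = cnv_association(pheno, copies)
        r2 = cnv_association(pheno, 2.0 * copies)
        assert r2.beta == pytest.approx(r1.beta / 2.0, rel=1e-10)
        assert r2.p == pytest.approx(r1.p, rel=1e-10)

    def test_shuffled_copies_are_null(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pheno, copies = _pheno_with_copies(n=120, effect=15.0, seed=seed)
            r = cnv_association(pheno, rng.permutation(copies))
            ps.append(r.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_copies_raise(self):
        pheno, copies = _pheno_with_copies(seed=2)
        with pytest.raises(ValueError, match="constant"):
            cnv_association(pheno, np.full(len(pheno), 2.0))

    def test_fixed_effects_matches_polygenic_free_mixed_model(self):
        """OLS route equals the score test with an identity kinship."""
        from cnvqtl.mixedmodel import KinshipMatrix

        pheno, copies = _pheno_with_copies(n=150, effect=0.5, seed=3)
        kin = KinshipMatrix(list(pheno["sample_id"]), np.eye(150))
        r_ols = cnv_association(pheno, copies)
        r_mm = cnv_association(pheno, copies, kin=kin)
        assert r_mm.beta == pytest.approx(r_ols.beta, rel=1e-8)
        # near the null the score and Wald variance estimates coincide
        assert r_mm.chi2 == pytest.approx(r_ols.chi2, rel=0.05)


class TestInteractionTest:
    @staticmethod
    def _two_locus(n=200, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ppard = rng.choice(["CC", "CT", "TT"], size=n)
        copies = rng.choice([2, 3, 4], size=n)
        ppard_num = np.array([{"CC": 0, "CT": 1, "TT": 2}[g] for g in ppard])
        y = (130.0 + 8.0 * ppard_num + 15.0 * (copies - 2)
             + interaction * ppard_num * (copies - 2)
             + rng.normal(0, 10, n))
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "ear_area": y,
            "ppard_genotype": ppard,
            "cnv_copies": copies,
            "sex": rng.integers(0, 2, n),
            "batch": rng.integers(1, 4, n),
            "carcass_weight": rng.normal(90, 8, n),
        })

    def test_type_one_error_under_additive_model(self):
        """Purely additive loci: interaction rejected at ~nominal 5% rate."""
        hits = 0
        n_rep = 300
        for seed in range(n_rep):
            out = interaction_test(self._two_locus(seed=seed))
            hits += out["p_interaction"] < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_power_against_product_effect(self):
        hits = 0
        for seed in range(40):
            out = interaction_test(self._two_locus(interaction=10.0,
                                                   seed=seed))
            hits += out["p_interaction"] < 0.05
        assert hits >= 32  # power > 0.8

    def test_main_effects_detected(self):
        out = interaction_test(self._two_locus(seed=5))
        assert out["p_main_a"] < 1e-4
        assert out["p_main_b"] < 1e-4

    def test_monomorphic_locus_raises(self):
        df = self._two_locus(seed=6)
        df["ppard_genotype"] = "CC"
        with pytest.raises(ValueError, match="single level"):
            interaction_test(df)


class TestConcordance:
    def test_founder_classes_fully_concordant(self):
        copies = [2, 2, 3, 3, 3] + [4] * 14
        qtl = ["qq", "qq", "Qq", "Qq", "Qq"] + ["QQ"] * 14
        assert concordance(copies, qtl) == 1.0

    def test_one_discordant_of_nineteen(self):
        copies = [2, 2, 3, 3, 3] + [4] * 14
        qtl = ["Qq", "qq", "Qq", "Qq", "Qq"] + ["QQ"] * 14
        assert concordance(copies, qtl) == pytest.approx(18 / 19)

    def test_identical_vectors(self):
        assert concordance([2, 3, 4, 6], [2, 3, 4, 6]) == 1.0

    def test_symmetric_and_relabel_invariant(self):
        a = [2, 3, 4, 4, 2]
        b = ["-/-", "+/-", "+/+", "+/+", "-/-"]
        assert concordance(a, b) == concordance(b, a) == 1.0

    def test_six_copies_class_as_homozygous(self):
        assert concordance([6, 6], ["QQ", "QQ"]) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            concordance([], [])


class TestAdjustExpression:
    def test_no_covariate_effects_returns_centred_values(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(200)],
            "value": rng.lognormal(0.0, 0.5, 200),
            "sex": rng.integers(0, 2, 200),
            "batch": rng.integers(1, 4, 200),
        })
        resid = adjust_expression(expr)
        centred = np.log2(expr["value"]) - np.log2(expr["value"]).mean()
        assert np.corrcoef(resid, centred)[0, 1] > 0.99

    def test_log_scale_flag_changes_results(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(80)],
            "value": rng.lognormal(0.0, 0.5, 80),
            "sex": rng.integers(0, 2, 80),
            "batch": rng.integers(1, 3, 80),
        })
        r_log = adjust_expression(expr)
        r_raw = adjust_expression(expr, log2_scale=False)
        assert not np.allclose(r_log, r_raw)

    def test_nonpositive_expression_rejected_on_log_scale(self):
        expr = pd.DataFrame({"sample_id": ["a", "b"], "value": [1.0, 0.0],
                             "sex": [0, 1], "batch": [1, 1]})
        with pytest.raises(ValueError, match="> 0"):
            adjust_expression(expr, covariates=())


class TestEqtlScan:
    def test_cnv_outranks_tag_snps(self):
        """Copy-number-driven expression: the CNV attains the best P among
        CNV + tag SNPs in most replicates."""
        wins = 0
        n_rep = 15
        for seed in range(n_rep):
            geno, truth = simulate_population(96, 35, block_size=35,
                                              seed=seed, ld_rho=0.97)
            copies = truth.causal_copies_per_sample
            expr = simulate_expression(copies, fold_per_copy=1.5,
                                       noise_sd=0.25, seed=seed + 10_000,
                                       sample_ids=geno.sample_ids)
            resid = adjust_expression(expr, covariates=())
            results, threshold = eqtl_scan(resid, geno,
                                           copies.astype(float),
                                           kinship(geno))
            assert threshold == pytest.approx(0.05 / 36)
            wins += min(results, key=lambda r: r.p).variant_id == "CNV"
        assert wins >= 12

    def test_tags_stay_below_perfect_ld(self):
        geno, truth = simulate_population(96, 35, block_size=35, seed=0,
                                          ld_rho=0.97)
        copies = truth.causal_copies_per_sample.astype(float)
        r2 = [ld_r2(geno.dosage[:, j], copies) for j in range(35)]
        assert max(r2) < 0.97
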