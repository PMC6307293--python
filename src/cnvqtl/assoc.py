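"""CNV association, two-locus interaction, genotype concordance, and eQTL
mapping of a copy-number-driven transcript.

The CNV association fits the fixed-effects linear model
y = u + sex + batch + cw + CNV + e with the relative quantity (or copy
number) as a quantitative covariate; an optional polygenic mode adds the
kinship random effect through the mixed-model scan. The two-locus
interaction test compares the full model with a locus-by-locus product term
against the additive model by an F-test. Expression values are pre-adjusted
for sex and batch with a Huber robust regression before the mixed-model
eQTL scan, in which the CNV competes against the tag SNPs with kinship in
the random effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .containers import AssociationResult, GenotypeMatrix
from .mixedmodel import (
    KinshipMatrix,
    NullModelFit,
    bonferroni_threshold,
    build_design,
    fit_null,
    score_scan,
    variance_explained,
)
from .quantify import genotype_from_copies

__all__ = [
    "cnv_association",
    "interaction_test",
    "concordance",
    "adjust_expression",
    "eqtl_scan",
]


def cnv_association(phenotypes: pd.DataFrame, rq_values: np.ndarray,
                    covariates: tuple[str, ...] = ("sex", "batch",
                                                   "carcass_weight"),
                    response: str = "ear_area",
                    kin: KinshipMatrix | None = None) -> AssociationResult:
    """Test the CNV term (RQ or copies) given sex, batch and weight.

    Default is the fixed-effects linear model; passing a kinship switches to
    the polygenic mixed-model score test on the same design. The returned
    result carries the variance explained by the term as computed from the
    residual-variance contrast of the reduced and full fixed-effects models.
    """
    rq = np.asarray(rq_values, dtype=float)
    if not np.isfinite(rq).all():
        raise ValueError("RQ values must be finite")
    if rq.std() == 0:
        raise ValueError("RQ values are constant; association undefined")
    y = phenotypes[response].to_numpy(dtype=float)
    X_cov, _ = build_design(phenotypes, covariates)

    if kin is None:
        X = np.column_stack([X_cov, rq])
        fit = sm.OLS(y, X).fit()
        beta = float(fit.params[-1])
        se = float(fit.bse[-1])
        result = AssociationResult.from_chi2("CNV", beta, se, (beta / se) ** 2)
    else:
        null = fit_null(phenotypes, covariates, kin, response=response)
        from .mixedmodel import _score_statistics

        xPy, xPx = _score_statistics(null, rq[:, None], null.X)
        beta = float(xPy[0] / xPx[0])
        se = float(1.0 / np.sqrt(xPx[0]))
        result = AssociationResult.from_chi2("CNV", beta, se,
                                             xPy[0] ** 2 / xPx[0])
    result.flag = ""
    # attach variance explained on the fixed-effects scale
    result.variance_explained = variance_explained(y, X_cov[:, 1:], rq)
    return result


def interaction_test(two_locus_table: pd.DataFrame,
                     locus_a: str = "ppard_genotype",
                     locus_b: str = "cnv_copies",
                     covariates: tuple[str, ...] = ("sex", "batch",
                                                    "carcass_weight"),
                     response: str = "ear_area") -> dict:
    """F-test of the locus-a x locus-b interaction over the additive model.

    Both loci enter as fixed factors; main-effect P-values come from the
    additive model's ANOVA, the interaction P from the full-vs-reduced
    F-test. An inestimable interaction (degenerate factor) raises.
    """
    df = two_locus_table.copy()
    for locus in (locus_a, locus_b):
        df[locus] = df[locus].astype("category")
        if df[locus].nunique() < 2:
            raise ValueError(f"locus {locus!r} has a single level; "
                             "interaction inestimable")
    cov_terms = [f"C({c})" if c in ("sex", "batch") else c for c in covariates]
    base = f"{response} ~ " + " + ".join(cov_terms + [f"C({locus_a})",
                                                      f"C({locus_b})"])
    full_formula = base + f" + C({locus_a}):C({locus_b})"
    reduced = smf.ols(base, data=df).fit()
    full = smf.ols(full_formula, data=df).fit()
    if full.df_resid <= 0 or full.df_model <= reduced.df_model:
        raise ValueError("interaction term inestimable on this design")
    anova = sm.stats.anova_lm(reduced, full)
    f_p = float(anova["Pr(>F)"].iloc[1])
    main = sm.stats.anova_lm(reduced, typ=2)
    return {
        "p_main_a": float(main.loc[f"C({locus_a})", "PR(>F)"]),
        "p_main_b": float(main.loc[f"C({locus_b})", "PR(>F)"]),
        "p_interaction": f_p,
        "f_statistic": float(anova["F"].iloc[1]),
        "df_interaction": float(anova["df_diff"].iloc[1]),
    }


_GENOTYPE_ALIASES = {
    "wild": "wild", "het": "het", "hom": "hom", "loss": "loss",
    "-/-": "wild", "+/-": "het", "+/+": "hom", "±": "het",
    "qq": "wild", "Qq": "het", "qQ": "het", "QQ": "hom",
}


def _canonical_genotypes(calls) -> list[str]:
    out = []
    for c in calls:
        if isinstance(c, str):
            if c not in _GENOTYPE_ALIASES:
                raise ValueError(f"unknown genotype label {c!r}")
            out.append(_GENOTYPE_ALIASES[c])
        else:
            out.append(genotype_from_copies(float(c)))
    return out


def concordance(cnv_genotypes, qtl_genotypes) -> float:
    """Fraction of samples whose CNV and QTL genotype classes agree.

    Copy numbers map to classes as {2 -> qq, 3 -> Qq, >= 4 -> QQ}; string
    labels (qq/Qq/QQ, -/-, +/-, +/+, wild/het/hom) are canonicalised, so
    the comparison is symmetric in its arguments.
    """
    a = _canonical_genotypes(cnv_genotypes)
    b = _canonical_genotypes(qtl_genotypes)
    if len(a) != len(b):
        raise ValueError("genotype vectors differ in length")
    if not a:
        raise ValueError("no overlapping genotype calls")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def adjust_expression(expression: pd.DataFrame,
                      covariates: tuple[str, ...] = ("sex", "batch"),
                      log2_scale: bool = True,
                      value_col: str = "value") -> np.ndarray:
    """Residualise expression on covariates with a Huber robust regression.

    Values (2^-DDCt units, multiplicative) are modelled on the log2 scale by
    default; residuals from an M-estimated (Huber, c = 1.345) linear fit on
    sex and batch are returned, in the model scale.
    """
    v = expression[value_col].to_numpy(dtype=float)
    if np.any(v <= 0) and log2_scale:
        raise ValueError("expression values must be > 0 for log2 modelling")
    y = np.log2(v) if log2_scale else v
    if covariates:
        X, _ = build_design(expression, covariates)
    else:
        X = np.ones((len(y), 1))
    if len(y) <= X.shape[1]:
        raise ValueError("fewer samples than covariate parameters")
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return np.asarray(y - rlm.fittedvalues)


def eqtl_scan(expression_resid: np.ndarray, genotypes: GenotypeMatrix,
              cnv_copies: np.ndarray, kin: KinshipMatrix,
              cnv_position: int | None = None, alpha: float = 0.05
              ) -> tuple[list[AssociationResult], float]:
    """Mixed-model eQTL scan of the tag SNPs plus the CNV itself.

    The adjusted expression is the response of an intercept-only polygenic
    null model; every SNP and the CNV copy-number vector (shifted to a
    0/1/2 dosage) are score-tested against it. Returns the results (CNV
    under variant id "CNV") and the Bonferroni threshold over all tests.
    """
    resid = np.asarray(expression_resid, dtype=float)
    if len(resid) != genotypes.n_samples:
        raise ValueError("expression and genotype samples differ")
    pheno = pd.DataFrame({"sample_id": genotypes.sample_ids,
                          "ear_area": resid})
    null = fit_null(pheno, (), kin)
    results = score_scan(genotypes, null)

    copies = np.asarray(cnv_copies, dtype=float)
    from .mixedmodel import _score_statistics

    xPy, xPx = _score_statistics(null, (copies - 2.0)[:, None], null.X)
    if xPx[0] <= 1e-10:
        results.append(AssociationResult("CNV", 0.0, float("nan"), 0.0, 1.0,
                                         0.0, flag="monomorphic"))
    else:
        results.append(AssociationResult.from_chi2(
            "CNV", float(xPy[0] / xPx[0]), float(1.0 / np.sqrt(xPx[0])),
            xPy[0] ** 2 / xPx[0]))
    threshold = bonferroni_threshold(alpha, len(results))
    return results, threshold
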