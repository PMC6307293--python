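"""Polygenic mixed-model association scans.

The model is y = Xb + g + e with g ~ N(0, sigma_g^2 K) for a genome-wide
identity-by-state kinship K and e ~ N(0, sigma_e^2 I). Variance components
are estimated once on the null model by REML, profiling the total variance
and optimising the heritability ratio on the eigenbasis of K (a single 1-D
bounded optimisation). Each SNP is then tested with the generalised
least-squares score statistic

    U = x' P y,   chi2 = U^2 / (x' P x),   beta = U / (x' P x),

where P is the inverse fitted covariance projected orthogonal to the fixed
effects — the classic two-step "mmscore" approximation used for family-based
GWAS. When sigma_g^2 = 0 and K = I this reduces exactly to the OLS Wald
test.

LOD is defined throughout as -log10(P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import AssociationResult, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "NullModelFit",
    "kinship",
    "build_design",
    "fit_null",
    "score_scan",
    "conditional_scan",
    "genomic_lambda",
    "variance_explained",
]

CHI2_1DF_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution

DEFAULT_COVARIATES = ("sex", "batch", "carcass_weight")
FACTOR_COVARIATES = {"sex", "batch"}


@dataclass
class KinshipMatrix:
    """Symmetric pairwise genotype-similarity matrix (polygenic covariance)."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be n x n")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


def kinship(genotypes: GenotypeMatrix, weighting: str = "frequency"
            ) -> KinshipMatrix:
    """Genome-wide identity-by-state kinship.

    weighting="raw": per-SNP IBS 1 - |g_i - g_j| / 2 averaged over SNPs,
    missing genotypes pairwise-deleted. weighting="frequency":
    allele-frequency-standardised relationship matrix Z Z' / m with
    Z = (G - 2p) / sqrt(2 p (1 - p)) and missing dosages imputed at 2p.
    """
    G = genotypes.dosage
    n, m = G.shape
    if n < 2 or m < 1:
        raise ValueError("kinship needs >= 2 samples and >= 1 SNP")
    miss = np.isnan(G)

    if weighting == "raw":
        # sum |g_i - g_j| over overlapping SNPs via dosage-class indicators
        A = [( (G == k) & ~miss ).astype(float) for k in (0.0, 1.0, 2.0)]
        obs = (~miss).astype(float)
        overlap = obs @ obs.T
        if np.any(overlap == 0):
            i, j = np.argwhere(overlap == 0)[0]
            raise ValueError(
                f"samples {genotypes.sample_ids[i]} and "
                f"{genotypes.sample_ids[j]} share no genotyped SNP"
            )
        absdiff = (
            A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
            + 2.0 * (A[0] @ A[2].T + A[2] @ A[0].T)
        )
        K = 1.0 - absdiff / (2.0 * overlap)
    elif weighting == "frequency":
        p = np.nanmean(G, axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if not poly.any():
            raise ValueError("all SNPs monomorphic; kinship undefined")
        Gp, pp = G[:, poly], p[poly]
        Z = np.where(np.isnan(Gp), 0.0, Gp - 2.0 * pp)
        Z /= np.sqrt(2.0 * pp * (1.0 - pp))
        K = (Z @ Z.T) / poly.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return KinshipMatrix(list(genotypes.sample_ids), (K + K.T) / 2.0)


def build_design(phenotypes: pd.DataFrame,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES
                 ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept + treatment-coded factors.

    Columns listed in FACTOR_COVARIATES (sex, batch) are dummy-coded with
    the first level as reference; the rest enter as numeric covariates.
    """
    cols: list[np.ndarray] = [np.ones(len(phenotypes))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise KeyError(f"covariate column {cov!r} missing from phenotypes")
        if cov in FACTOR_COVARIATES:
            dummies = pd.get_dummies(phenotypes[cov].astype("category"),
                                     drop_first=True, dtype=float)
            for level in dummies.columns:
                cols.append(dummies[level].to_numpy())
                names.append(f"{cov}[{level}]")
        else:
            cols.append(phenotypes[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in the fixed-effect design")
    return X, names


@dataclass
class NullModelFit:
    """REML fit of the covariate-only mixed model, reusable across scans."""

    sample_ids: list[str]
    y: np.ndarray
    X: np.ndarray
    coef_names: list[str]
    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    residuals: np.ndarray
    eig_vectors: np.ndarray  # eigenbasis U of the (PSD-fixed) kinship
    eig_values: np.ndarray  # eigenvalues s, clipped at 0
    rotated_weights: np.ndarray  # fitted variances sigma_g2*s + sigma_e2

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    def fitted(self) -> np.ndarray:
        return self.X @ self.beta


def _reml_neg_loglik(h: float, ys: np.ndarray, Xs: np.ndarray,
                     s: np.ndarray) -> float:
    n, p = Xs.shape
    w = h * s + (1.0 - h)
    Wi = 1.0 / w
    XtWX = Xs.T @ (Wi[:, None] * Xs)
    XtWy = Xs.T @ (Wi * ys)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(r @ (Wi * r))
    sigma2 = rss / (n - p)
    _, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * np.log(sigma2)
        + np.log(w).sum()
        + logdet_XtWX
        + (n - p)
    )
    return -ll


def fit_null(phenotypes: pd.DataFrame, covariates: tuple[str, ...],
             kin: KinshipMatrix, response: str = "ear_area") -> NullModelFit:
    """REML variance components and GLS fixed effects under cov = s2g*K + s2e*I.

    The kinship is made positive semidefinite by clipping negative
    eigenvalues at zero; the heritability ratio is optimised on (0, 1) by a
    bounded 1-D search on the eigenbasis, with the boundary h = 0 (pure OLS)
    also evaluated.
    """
    if list(phenotypes["sample_id"]) != list(kin.sample_ids):
        raise ValueError("phenotype and kinship sample order differ")
    y = phenotypes[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")
    X, names = build_design(phenotypes, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer samples than fixed-effect parameters")

    s, U = np.linalg.eigh(kin.values)
    s = np.clip(s, 0.0, None)  # PSD fixup: raw IBS can be indefinite
    ys, Xs = U.T @ y, U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(1e-9, 1.0 - 1e-9), args=(ys, Xs, s),
        method="bounded", options={"xatol": 1e-8},
    )
    h = float(res.x)
    # prefer the h -> 0 boundary when it is at least as likely (no polygenic term)
    if _reml_neg_loglik(1e-12, ys, Xs, s) <= res.fun + 1e-9:
        h = 0.0
    w = h * s + (1.0 - h)
    Wi = 1.0 / w
    XtWX = Xs.T @ (Wi[:, None] * Xs)
    beta = np.linalg.solve(XtWX, Xs.T @ (Wi * ys))
    r = ys - Xs @ beta
    sigma2 = float(r @ (Wi * r)) / (n - p)
    return NullModelFit(
        sample_ids=list(phenotypes["sample_id"]),
        y=y,
        X=X,
        coef_names=names,
        beta=beta,
        sigma_g2=sigma2 * h,
        sigma_e2=sigma2 * (1.0 - h),
        reml_loglik=-_reml_neg_loglik(max(h, 1e-12), ys, Xs, s),
        residuals=y - X @ beta,
        eig_vectors=U,
        eig_values=s,
        rotated_weights=sigma2 * w,
    )


def _impute_dosages(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per SNP (post-QC missingness is small)."""
    if not np.isnan(G).any():
        return G
    G = G.copy()
    means = np.nanmean(G, axis=0)
    idx = np.where(np.isnan(G))
    G[idx] = means[idx[1]]
    return G


def _score_statistics(null_fit: NullModelFit, G: np.ndarray, X: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(x'Py, x'Px) per column of G, for P projected orthogonal to X."""
    U = null_fit.eig_vectors
    Wi = 1.0 / null_fit.rotated_weights
    ys = U.T @ null_fit.y
    Xs = U.T @ X
    Gs = U.T @ G
    XtWX = Xs.T @ (Wi[:, None] * Xs)
    XtWX_inv = np.linalg.inv(XtWX)
    XtWy = Xs.T @ (Wi * ys)
    Py = Wi * (ys - Xs @ (XtWX_inv @ XtWy))  # V^-1 (y - X b_gls)
    B = Xs.T @ (Wi[:, None] * Gs)  # p x m
    xPy = Gs.T @ Py
    xWx = np.einsum("ij,ij->j", Gs, Wi[:, None] * Gs)
    xPx = xWx - np.einsum("ij,ij->j", B, XtWX_inv @ B)
    return xPy, xPx


def score_scan(genotypes: GenotypeMatrix, null_fit: NullModelFit
               ) -> list[AssociationResult]:
    """Mixed-model score test of every SNP against the fitted null."""
    if genotypes.sample_ids != null_fit.sample_ids:
        raise ValueError("genotype and null-model samples differ")
    G = _impute_dosages(genotypes.dosage)
    xPy, xPx = _score_statistics(null_fit, G, null_fit.X)
    results = []
    for j, vid in enumerate(genotypes.snp_ids):
        if np.nanstd(G[:, j]) == 0 or xPx[j] <= 1e-10:
            results.append(AssociationResult(vid, 0.0, float("nan"), 0.0, 1.0,
                                             0.0, flag="monomorphic"))
            continue
        beta = xPy[j] / xPx[j]
        se = 1.0 / np.sqrt(xPx[j])
        results.append(
            AssociationResult.from_chi2(vid, beta, se, xPy[j] ** 2 / xPx[j])
        )
    return results


def conditional_scan(genotypes: GenotypeMatrix, null_fit: NullModelFit,
                     conditioning: np.ndarray,
                     conditioning_names: list[str] | None = None
                     ) -> list[AssociationResult]:
    """Score scan with extra columns added to the fixed effects.

    ``conditioning`` is n x k (e.g. dosages of candidate causal variants, or
    CNV copy numbers). Variance components from the null fit are reused; the
    fixed-effect projection is widened. A tested SNP collinear with the
    conditioning columns is flagged rather than tested.
    """
    if genotypes.sample_ids != null_fit.sample_ids:
        raise ValueError("genotype and null-model samples differ")
    C = np.atleast_2d(np.asarray(conditioning, dtype=float))
    if C.shape[0] != len(null_fit.sample_ids):
        C = C.T
    if C.shape[0] != len(null_fit.sample_ids):
        raise ValueError("conditioning rows must match samples")
    X_aug = np.column_stack([null_fit.X, C])
    if np.linalg.matrix_rank(X_aug) < X_aug.shape[1]:
        raise ValueError("conditioning columns collinear with covariates")

    G = _impute_dosages(genotypes.dosage)
    xPy, xPx = _score_statistics(null_fit, G, X_aug)
    # collinearity scale: x'Px relative to the SNP's own weighted variance
    results = []
    for j, vid in enumerate(genotypes.snp_ids):
        var_x = np.nanstd(G[:, j]) ** 2
        if var_x == 0:
            results.append(AssociationResult(vid, 0.0, float("nan"), 0.0, 1.0,
                                             0.0, flag="monomorphic"))
            continue
        if xPx[j] <= 1e-8 * var_x * len(null_fit.sample_ids):
            results.append(AssociationResult(vid, 0.0, float("nan"), 0.0, 1.0,
                                             0.0, flag="collinear"))
            continue
        beta = xPy[j] / xPx[j]
        se = 1.0 / np.sqrt(xPx[j])
        results.append(
            AssociationResult.from_chi2(vid, beta, se, xPy[j] ** 2 / xPx[j])
        )
    return results


def genomic_lambda(chi2_values: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2 over the chi2(1) median."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    chi2_values = chi2_values[np.isfinite(chi2_values)]
    if chi2_values.size == 0:
        raise ValueError("no chi-square values")
    return float(np.median(chi2_values) / CHI2_1DF_MEDIAN)


def variance_explained(y: np.ndarray, covariates: np.ndarray,
                       term: np.ndarray) -> float:
    """Residual-variance reduction (V_reduce - V_full) / V_reduce.

    V_reduce is the residual variance of y on the covariates alone, V_full
    adds the tested term (e.g. top-SNP genotype or CNV copy number).
    """
    y = np.asarray(y, dtype=float)
    Xr = np.column_stack([np.ones(len(y)), np.atleast_2d(covariates).reshape(len(y), -1)]) \
        if covariates is not None and np.size(covariates) else np.ones((len(y), 1))
    t = np.asarray(term, dtype=float).reshape(len(y), -1)
    Xf = np.column_stack([Xr, t])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("term collinear with covariates")

    def _resid_var(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r) / (len(y) - X.shape[1])

    v_reduce = _resid_var(Xr)
    if v_reduce == 0:
        raise ValueError("reduced model has zero residual variance")
    v_full = _resid_var(Xf)
    return (v_reduce - v_full) / v_reduce


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def scan_summary(results: list[AssociationResult], alpha: float = 0.05) -> dict:
    """Genomic-control lambda, test count and Bonferroni threshold for a scan."""
    chi2 = np.array([r.chi2 for r in results if not r.flag])
    return {
        "lambda_gc": genomic_lambda(chi2),
        "n_tests": int(chi2.size),
        "bonferroni_threshold": bonferroni_threshold(alpha, max(int(chi2.size), 1)),
    }
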