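"""Haplotype-sharing analysis: shared segments, carrier-exclusive segments,
and haplotype effect tests.

Shared segments are maximal runs of consecutive SNPs at which every carrier
haplotype carries the same allele. By default a missing allele breaks a run
(conservative); the permissive mode lets missing match anything. A shared
segment is carrier-exclusive when no control haplotype reproduces the
carrier allele run in full. Segment endpoints are reported at the outermost
matching SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import HaplotypeSet, Interval

__all__ = ["shared_segments", "exclusive_segments", "haplotype_effect_test"]


def _consensus_run_mask(alleles: np.ndarray, missing_matches: bool
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(is_shared per SNP, consensus allele per SNP; -1 where not shared)."""
    obs = np.ma.masked_equal(alleles, -1)
    if missing_matches:
        mn, mx = obs.min(axis=0), obs.max(axis=0)
        shared = ~(mn.mask | (mn != mx)).filled(True)  # all-missing column: not shared
        consensus = np.where(shared, mn.filled(-1), -1)
    else:
        any_missing = (alleles == -1).any(axis=0)
        same = (alleles == alleles[0, :]).all(axis=0)
        shared = same & ~any_missing
        consensus = np.where(shared, alleles[0, :], -1)
    return shared, consensus.astype(np.int8)


def shared_segments(carriers: HaplotypeSet, min_snps: int = 2,
                    missing_matches: bool = False) -> list[Interval]:
    """Maximal runs of SNPs at which all carrier haplotypes agree.

    Returns positional intervals (span of the outermost matching SNPs);
    runs of fewer than ``min_snps`` SNPs are dropped.
    """
    if carriers.n_haplotypes < 2:
        raise ValueError("need >= 2 carrier haplotypes")
    shared, _ = _consensus_run_mask(carriers.alleles, missing_matches)
    segments = []
    m = len(shared)
    j = 0
    while j < m:
        if shared[j]:
            k = j
            while k + 1 < m and shared[k + 1]:
                k += 1
            if k - j + 1 >= min_snps:
                segments.append(Interval(carriers.chrom,
                                         int(carriers.pos[j]),
                                         int(carriers.pos[k])))
            j = k + 1
        else:
            j += 1
    return segments


def exclusive_segments(shared: list[Interval], carriers: HaplotypeSet,
                       controls: HaplotypeSet | None,
                       missing_matches: bool = False) -> list[Interval]:
    """Shared segments whose carrier allele run no control haplotype matches.

    With no controls supplied, the shared segments are returned unchanged.
    A control with a missing allele inside the segment counts as matching
    only in permissive mode.
    """
    if controls is None or controls.n_haplotypes == 0:
        return list(shared)
    if list(controls.snp_ids) != list(carriers.snp_ids):
        raise ValueError("carriers and controls must share the SNP panel")
    _, consensus = _consensus_run_mask(carriers.alleles, missing_matches)
    kept = []
    for seg in shared:
        idx = np.flatnonzero((carriers.pos >= seg.start) & (carriers.pos <= seg.end))
        cons = consensus[idx]
        ctrl = controls.alleles[:, idx]
        if missing_matches:
            match = ((ctrl == cons[None, :]) | (ctrl == -1)).all(axis=1)
        else:
            match = (ctrl == cons[None, :]).all(axis=1)
        if not match.any():
            kept.append(seg)
    return kept


def haplotype_effect_test(phenotypes: pd.DataFrame,
                          diplotype_labels: pd.DataFrame,
                          covariates: tuple[str, ...] = (),
                          response: str = "ear_area") -> dict:
    """Least-square means per haplotype class and pairwise contrast t-tests.

    ``diplotype_labels`` has columns sample_id, hap1, hap2 (class label of
    each of the sample's two haplotypes). The phenotype is regressed on the
    per-sample copy count of each haplotype class (plus covariates); the
    least-square mean of class q is the model prediction for a two-copy q
    carrier at covariate means, and pairwise contrasts are t-tests on
    coefficient differences. Classes observed on fewer than 2 haplotypes are
    excluded with a warning field in the output.
    """
    from .mixedmodel import build_design

    merged = phenotypes.merge(diplotype_labels, on="sample_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping samples")
    labels = pd.concat([merged["hap1"], merged["hap2"]])
    counts = labels.value_counts()
    classes = sorted(counts[counts >= 2].index)
    excluded = sorted(counts[counts < 2].index)
    if not classes:
        raise ValueError("no haplotype class observed on >= 2 chromosomes")

    # per-sample copy count of each class; first class absorbed in intercept
    copy_counts = np.column_stack([
        (merged["hap1"] == c).to_numpy(int) + (merged["hap2"] == c).to_numpy(int)
        for c in classes
    ])
    X_cov, cov_names = (build_design(merged, covariates) if covariates
                        else (np.ones((len(merged), 1)), ["intercept"]))
    X = np.column_stack([X_cov, copy_counts[:, 1:]])
    names = cov_names + [f"copies[{c}]" for c in classes[1:]]
    y = merged[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()

    # least-square mean of a 2-copy carrier of each class, covariates at mean
    base = X_cov.mean(axis=0) @ fit.params[: X_cov.shape[1]]
    coef = np.concatenate([[0.0], fit.params[X_cov.shape[1]:]])  # per-class effect
    cov_beta = fit.cov_params()
    k0 = X_cov.shape[1]
    lsmeans = {}
    for i, c in enumerate(classes):
        mean = base + 2.0 * coef[i]
        var = 0.0 if i == 0 else 4.0 * cov_beta[k0 + i - 1, k0 + i - 1]
        lsmeans[c] = {"lsmean": float(mean), "se": float(np.sqrt(var))}

    contrasts = {}
    if len(classes) >= 2:
        from scipy import stats as sps

        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                L = np.zeros(X.shape[1])
                if i > 0:
                    L[k0 + i - 1] = 2.0
                if j > 0:
                    L[k0 + j - 1] -= 2.0
                est = float(L @ fit.params)
                se = float(np.sqrt(L @ cov_beta @ L))
                t = est / se if se > 0 else np.inf
                p = 2 * sps.t.sf(abs(t), df=fit.df_resid)
                contrasts[(classes[i], classes[j])] = {
                    "difference": est, "se": se, "t": float(t), "p": float(p),
                }

    return {
        "classes": classes,
        "excluded_classes": excluded,
        "lsmeans": lsmeans,
        "contrasts": contrasts,
        "model": fit,
        "coef_names": names,
    }
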