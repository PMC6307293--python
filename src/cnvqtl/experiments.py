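"""Canonical reproducibility experiments for the whole pipeline.

Each function re-runs one self-contained synthetic experiment from a seed:
the worked copy-number-variant length, two-population fine-mapping logic
(confidence interval, haplotype refinement, conditional scan), null
calibration of the scan and of the chi-square-sum meta-analysis, effect
and copy-number recovery, and the read-depth caller's breakpoint accuracy.
The acceptance script and the test suite both call these, so the numbers
they report are always produced by the same code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assoc import adjust_expression, cnv_association, eqtl_scan, interaction_test
from .containers import Interval
from .depthcnv import CallerParams, call_cnvs
from .haplotypes import exclusive_segments, shared_segments
from .intervals import confidence_interval, intersect
from .meta import meta_chi2
from .mixedmodel import fit_null, genomic_lambda, kinship, score_scan, conditional_scan
from .simulate import (
    simulate_ddpcr,
    simulate_depth_track,
    simulate_expression,
    simulate_phenotypes,
    simulate_population,
    simulate_qpcr,
)
from .quantify import ddpcr_copy_number, rq_from_ddct

COVARIATES = ("sex", "batch", "carcass_weight")

# breakpoints of the duplication as mapped by PCR + Sanger sequencing on the
# corrected contig; the classic worked example for interval arithmetic
CNV_BREAKPOINT_START = 349_577
CNV_BREAKPOINT_END = 388_246

# fine-mapped QTL: LD/LOD interval and large-ear shared haplotype segment
QTL_CI = Interval("5", 29_740_000, 30_250_000)
SHARED_SEGMENT = Interval("5", 29_580_000, 29_880_000)


def worked_cnv_length_kb() -> float:
    """Length of the duplication from its printed breakpoints, in kb."""
    iv = Interval("5", CNV_BREAKPOINT_START, CNV_BREAKPOINT_END)
    return round(iv.length / 1000.0, 1)


def interval_intersection_mb() -> tuple[float, float]:
    """Overlap of the QTL confidence interval with the shared segment (Mb)."""
    out = intersect(QTL_CI, SHARED_SEGMENT)
    return out.start / 1e6, out.end / 1e6


# ------------------------------------------------------------ fine mapping

def fine_mapping_replicate(seed: int, n_samples: int = 500,
                           n_snps: int = 600) -> dict:
    """One end-to-end fine-mapping replicate.

    Simulates a population with a causal 4-copy-capable duplication tagged
    by SNPs, scans it with the polygenic mixed model, builds the r2/2-LOD
    confidence interval, refines it with the founder haplotype-sharing
    segment, and re-scans conditional on the true copy numbers.
    """
    geno, truth = simulate_population(n_samples, n_snps, block_size=10,
                                      seed=seed)
    pheno = simulate_phenotypes(geno, truth)
    kin = kinship(geno)
    null = fit_null(pheno, COVARIATES, kin)
    results = score_scan(geno, null)
    clean = [r for r in results if not r.flag]
    peak = max(clean, key=lambda r: r.lod)
    ci = confidence_interval(results, geno, peak.variant_id)

    # founder-scale haplotype sharing: 14 carrier vs 14 control chromosomes
    haps = truth.haplotypes
    carrier_idx = np.flatnonzero(truth.cnv_hap_alleles == 1)[:14]
    control_idx = np.flatnonzero(truth.cnv_hap_alleles == 0)[:14]
    shared = shared_segments(haps.select(carrier_idx))
    exclusive = exclusive_segments(shared, haps.select(carrier_idx),
                                   haps.select(control_idx))
    seg_hits = [s for s in exclusive if s.contains(truth.causal_position)]
    refined = intersect(ci, seg_hits[0]) if seg_hits else None

    cond = conditional_scan(
        geno, null, truth.causal_copies_per_sample.astype(float)[:, None])
    gw_threshold = 0.05 / len(clean)
    region = Interval(truth.causal_chrom, truth.causal_position - 50_000,
                      truth.causal_position + 50_000)
    sig_before = [r for r, p in zip(results, geno.pos)
                  if not r.flag and r.p < gw_threshold
                  and region.contains(int(p))]
    sig_after = [r for r, p in zip(cond, geno.pos)
                 if not r.flag and r.p < gw_threshold
                 and region.contains(int(p))]

    return {
        "peak_lod": peak.lod,
        "ci": ci,
        "ci_contains_causal": ci.contains(truth.causal_position),
        "segment_contains_causal": bool(seg_hits),
        "refined_contains_causal": (refined is not None
                                    and refined.contains(truth.causal_position)),
        "n_significant_before": len(sig_before),
        "conditional_clears_region": bool(sig_before) and not sig_after,
        "heritability": null.heritability,
    }


def eqtl_replicate(seed: int, n_samples: int = 96, n_tags: int = 35) -> bool:
    """True when the CNV attains the best eQTL P among CNV + tag SNPs.

    Tags sit in one LD block at r2 ~<= 0.9 to the copy-number genotype; the
    transcript's expression scales 1.5-fold per extra copy.
    """
    geno, truth = simulate_population(n_samples, n_tags, block_size=n_tags,
                                      seed=seed, ld_rho=0.97)
    copies = truth.causal_copies_per_sample
    expr = simulate_expression(copies, fold_per_copy=1.5, noise_sd=0.25,
                               seed=seed + 10_000,
                               sample_ids=geno.sample_ids)
    resid = adjust_expression(expr, covariates=())
    results, _ = eqtl_scan(resid, geno, copies.astype(float), kinship(geno))
    return min(results, key=lambda r: r.p).variant_id == "CNV"


def caller_replicate(seed: int, tolerance_bp: int = 50) -> bool:
    """True when the 4-copy duplication is recovered to +-tolerance and CN 4."""
    cnv = (4_501, 5_500)
    track = simulate_depth_track(region_len=10_000, mean_depth=30.0,
                                 cnv_interval=cnv, copies=4, seed=seed)
    gains = [c for c in call_cnvs(track, CallerParams()) if c.type == "gain"]
    return (len(gains) == 1
            and abs(gains[0].interval.start - cnv[0]) <= tolerance_bp
            and abs(gains[0].interval.end - cnv[1]) <= tolerance_bp
            and gains[0].estimated_copies == 4)


# --------------------------------------------------------- null calibration

def null_scan_chi2(seed: int, n_samples: int = 300, n_snps: int = 2000
                   ) -> np.ndarray:
    """Chi-square values of one null GWAS (no causal effect, h2 = 0)."""
    geno, truth = simulate_population(n_samples, n_snps, block_size=1,
                                      seed=seed, effect_per_copy=0.0,
                                      polygenic_h2=0.0)
    pheno = simulate_phenotypes(geno, truth)
    null = fit_null(pheno, COVARIATES, kinship(geno))
    return np.array([r.chi2 for r in score_scan(geno, null) if not r.flag])


def null_calibration(seed: int, n_populations: int = 5) -> dict:
    """Null GWAS uniformity, pooled genomic lambda, and meta-chi2 uniformity."""
    per_pop = [null_scan_chi2(seed + k) for k in range(n_populations)]
    ks_gwas = stats.kstest(stats.chi2.sf(per_pop[0], df=1), "uniform").pvalue

    n_var = min(len(c) for c in per_pop)
    meta_p = np.array([
        meta_chi2({f"pop{k}": per_pop[k][j] for k in range(n_populations)}).p
        for j in range(n_var)
    ])
    ks_meta = stats.kstest(meta_p, "uniform").pvalue
    lam = genomic_lambda(np.concatenate(per_pop))
    return {"ks_p_gwas": float(ks_gwas), "ks_p_meta": float(ks_meta),
            "lambda_gc": float(lam), "n_variants": int(n_var)}


def interaction_type1_rate(seed: int, n_reps: int = 500, n: int = 200) -> float:
    """Type-I error of the two-locus interaction F-test under additivity."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        ppard = rng.choice(["CC", "CT", "TT"], size=n)
        copies = rng.choice([2, 3, 4], size=n)
        ppard_num = np.array([{"CC": 0, "CT": 1, "TT": 2}[g] for g in ppard])
        y = (130.0 + 8.0 * ppard_num + 15.0 * (copies - 2)
             + rng.normal(0, 10, n))
        table = pd.DataFrame({
            "sample_id": range(n), "ear_area": y, "ppard_genotype": ppard,
            "cnv_copies": copies, "sex": rng.integers(0, 2, n),
            "batch": rng.integers(1, 4, n),
            "carcass_weight": rng.normal(90, 8, n),
        })
        hits += interaction_test(table)["p_interaction"] < 0.05
    return hits / n_reps


# --------------------------------------------------------- recovery suites

def effect_recovery(seed: int, n_reps: int = 200, n: int = 400,
                    effect: float = 15.0) -> dict:
    """Per-copy effect estimates across replicates (fixed-effects model)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    betas = []
    for _ in range(n_reps):
        copies = rng.choice([2, 3, 4], size=n, p=[0.49, 0.42, 0.09])
        pheno = pd.DataFrame({
            "sample_id": range(n),
            "sex": rng.integers(0, 2, n),
            "batch": rng.integers(1, 5, n),
            "carcass_weight": rng.normal(90, 8, n),
        })
        pheno["ear_area"] = (130.0 + 12.0 * pheno["sex"]
                             + 4.0 * pheno["batch"]
                             + 0.6 * pheno["carcass_weight"]
                             + effect * (copies - 2)
                             + rng.normal(0, 10, n))
        betas.append(cnv_association(pheno, copies.astype(float)).beta)
    betas = np.array(betas)
    se = betas.std(ddof=1) / np.sqrt(n_reps)
    return {"mean_beta": float(betas.mean()), "se": float(se),
            "true_effect": effect,
            "deviation_in_se": float(abs(betas.mean() - effect) / se)}


def ddpcr_bias(seed: int, n_droplets: int = 1_000_000,
               copies_grid: tuple[int, ...] = (2, 3, 4, 6)) -> dict:
    """Relative bias of the Poisson estimator at large droplet counts."""
    out = {}
    for k, c in enumerate(copies_grid):
        well = simulate_ddpcr(c, n_droplets=n_droplets, ref_lambda=0.5,
                              seed=seed + k)
        out[c] = abs(ddpcr_copy_number(well) - c) / c
    return out


def qpcr_exact_inversion(copies_grid: tuple[int, ...] = (2, 3, 4)) -> dict:
    """Noiseless comparative-Ct round trip error (should be ~ machine zero)."""
    out = {}
    for c in copies_grid:
        m = simulate_qpcr(c, noise_sd=0.0, seed=0)
        _, est = rq_from_ddct(m)
        out[c] = abs(est - c)
    return out
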