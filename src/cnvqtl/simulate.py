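"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the downstream analyses
assume: multi-population biallelic genotypes with block LD around a causal
copy-number locus, an additive phenotype with sex/batch/weight covariates and
a polygenic term drawn against the realised kinship, per-base sequencing
depth with GC bias and a duplicated segment, droplet-digital-PCR wells with
Poisson occupancy, qPCR Ct triplicates, and copy-number-driven miRNA
expression.

LD blocks are generated with a latent Gaussian AR(1) copula per block: each
haplotype draws an autocorrelated latent chain and thresholds it at the
per-SNP allele-frequency quantile. This yields phased haplotypes, exact
control of marginal allele frequencies, and tunable adjacent-SNP r^2 through
the latent correlation, without simulating a coalescent. The causal
copy-number allele is embedded as one extra latent site inside its block, so
neighbouring SNPs tag it at high r^2 exactly as array SNPs tag an unobserved
structural variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DepthTrack, GenotypeMatrix, HaplotypeSet
from .quantify import DdpcrWell, QpcrMeasurement

__all__ = [
    "SimTruth",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_depth_track",
    "simulate_ddpcr",
    "simulate_qpcr",
    "simulate_expression",
]


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    ``causal_copies_per_sample`` holds the diploid copy number (2, 3 or 4)
    at the causal duplication; the per-haplotype duplication alleles and the
    phased SNP haplotypes are retained so that haplotype-sharing analyses can
    be run against truth.
    """

    causal_position: int
    causal_copies_per_sample: np.ndarray  # int, one per sample
    effect_per_copy: float  # phenotype units (cm^2) per extra copy
    polygenic_h2: float
    covariate_effects: dict[str, float]
    seed: int
    causal_chrom: str = "5"
    cnv_hap_alleles: np.ndarray | None = None  # 0/1 per haplotype
    haplotypes: HaplotypeSet | None = None
    mu: float = 130.0
    noise_var: float = 100.0  # polygenic + residual variance (cm^4)


_DEFAULT_COVARIATE_EFFECTS = {"sex": 12.0, "batch": 4.0, "carcass_weight": 0.6}


def _ar1_latent(rng: np.random.Generator, n_hap: int, length: int,
                rho: float) -> np.ndarray:
    """Latent AR(1) Gaussian chains, one per haplotype (rows)."""
    z = np.empty((n_hap, length))
    z[:, 0] = rng.standard_normal(n_hap)
    if length > 1:
        innov = rng.standard_normal((n_hap, length - 1))
        c = np.sqrt(1.0 - rho * rho)
        for k in range(1, length):
            z[:, k] = rho * z[:, k - 1] + c * innov[:, k - 1]
    return z


def simulate_population(
    n_samples: int = 500,
    n_snps: int = 300,
    block_size: int = 10,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    *,
    ld_rho: float = 0.99999,
    snp_spacing: int = 2_000,
    chrom: str = "5",
    cnv_allele_freq: float = 0.3,
    effect_per_copy: float = 15.0,
    polygenic_h2: float = 0.3,
    covariate_effects: dict[str, float] | None = None,
    mu: float = 130.0,
    noise_var: float = 100.0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate phased SNP genotypes with block LD and a causal duplication.

    SNPs are laid out in consecutive blocks of ``block_size``; within a
    block, haplotype alleles come from one autocorrelated latent chain
    (correlation ``ld_rho`` between adjacent sites), so adjacent-SNP r^2 is
    high inside blocks and zero across block boundaries. The causal
    duplication allele (frequency ``cnv_allele_freq``, Hardy-Weinberg
    diploid copies 2 + a1 + a2) is one extra latent site in the centre of the
    middle block; its physical position falls between the two flanking SNPs.

    Returns the dosage matrix plus the ground truth (copies per sample,
    per-haplotype duplication alleles, and the phased haplotypes).
    """
    if n_samples < 2 or n_snps < 2:
        raise ValueError("need n_samples >= 2 and n_snps >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not (0.0 < cnv_allele_freq < 1.0):
        raise ValueError("cnv_allele_freq must be in (0, 1)")

    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples

    # block layout over SNP indices
    starts = list(range(0, n_snps, block_size))
    blocks = [(s, min(s + block_size, n_snps)) for s in starts]
    causal_block = blocks[len(blocks) // 2]

    # one alt-allele frequency per block: SNPs tagging the same haplotype
    # share a frequency, which is what lets adjacent r^2 approach 1; the
    # causal block uses the duplication allele frequency so the tag SNPs
    # track the unobserved causal site
    p = np.empty(n_snps)
    for (b0, b1) in blocks:
        p[b0:b1] = min(max(cnv_allele_freq, lo), hi) \
            if (b0, b1) == causal_block else rng.uniform(lo, hi)

    alleles = np.empty((n_hap, n_snps), dtype=np.int8)
    cnv_alleles = np.zeros(n_hap, dtype=np.int8)
    causal_after = None  # SNP index the causal site follows

    for (b0, b1) in blocks:
        width = b1 - b0
        if (b0, b1) == causal_block and width >= 2:
            # insert the unobserved causal site mid-block in the latent chain
            k_ins = width // 2  # causal sits between SNPs b0+k_ins-1, b0+k_ins
            z = _ar1_latent(rng, n_hap, width + 1, ld_rho)
            zsnp = np.delete(z, k_ins, axis=1)
            zc = z[:, k_ins]
            cnv_alleles = (zc < stats.norm.ppf(cnv_allele_freq)).astype(np.int8)
            causal_after = b0 + k_ins - 1
        else:
            zsnp = _ar1_latent(rng, n_hap, width, ld_rho)
            if (b0, b1) == causal_block:  # width 1: tie causal to the lone SNP chain
                z2 = ld_rho * zsnp[:, 0] + np.sqrt(1 - ld_rho**2) * \
                    rng.standard_normal(n_hap)
                cnv_alleles = (z2 < stats.norm.ppf(cnv_allele_freq)).astype(np.int8)
                causal_after = b0
        thr = stats.norm.ppf(p[b0:b1])
        alleles[:, b0:b1] = (zsnp < thr[None, :]).astype(np.int8)
        if (b0, b1) == causal_block:
            # the duplication arose once: every carrier chromosome inherits
            # the same founder haplotype across its block (identity by
            # descent), which is what haplotype-sharing analysis exploits
            alleles[cnv_alleles == 1, b0:b1] = 1

    pos = np.arange(1, n_snps + 1, dtype=np.int64) * snp_spacing
    if causal_after is None:
        causal_after = n_snps // 2
    causal_position = int(pos[causal_after] + snp_spacing // 2)

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    snp_ids = [f"snp{j:05d}" for j in range(n_snps)]
    dosage = (alleles[0::2, :] + alleles[1::2, :]).astype(float)
    geno = GenotypeMatrix(sample_ids, snp_ids, np.full(n_snps, chrom, dtype=object),
                          pos, dosage)

    hap_ids = [f"{s}_h{a}" for s in sample_ids for a in (1, 2)]
    haps = HaplotypeSet(hap_ids, snp_ids, pos, alleles, chrom=chrom)
    copies = 2 + cnv_alleles[0::2] + cnv_alleles[1::2]

    truth = SimTruth(
        causal_position=causal_position,
        causal_copies_per_sample=copies.astype(int),
        effect_per_copy=effect_per_copy,
        polygenic_h2=polygenic_h2,
        covariate_effects=dict(_DEFAULT_COVARIATE_EFFECTS
                               if covariate_effects is None
                               else covariate_effects),
        seed=seed,
        causal_chrom=chrom,
        cnv_hap_alleles=cnv_alleles,
        haplotypes=haps,
        mu=mu,
        noise_var=noise_var,
    )
    return geno, truth


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: SimTruth,
                        n_batches: int = 4) -> pd.DataFrame:
    """Draw phenotypes under the additive model the association stage fits.

    ear_area = mu + sex + batch + b*carcass_weight + a*(copies - 2)
             + polygenic + residual,
    with the polygenic term drawn from N(0, sigma_g^2 * K) against the
    frequency-standardised kinship realised in ``genotypes`` and
    sigma_g^2 = h2 * noise_var, sigma_e^2 = (1 - h2) * noise_var.
    """
    n = genotypes.n_samples
    if len(truth.causal_copies_per_sample) != n:
        raise ValueError("truth copies and genotype samples do not match")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    eff = truth.covariate_effects

    sex = rng.integers(0, 2, size=n)
    batch = rng.integers(1, n_batches + 1, size=n)
    cw = rng.normal(90.0, 8.0, size=n)

    sigma_g2 = truth.polygenic_h2 * truth.noise_var
    sigma_e2 = (1.0 - truth.polygenic_h2) * truth.noise_var
    if sigma_g2 > 0:
        from .mixedmodel import kinship

        K = kinship(genotypes, weighting="frequency").values
        # jitter keeps the Cholesky stable on near-singular realised kinship
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        polygenic = np.sqrt(sigma_g2) * (L @ rng.standard_normal(n))
    else:
        polygenic = np.zeros(n)

    ear = (
        truth.mu
        + eff.get("sex", 0.0) * sex
        + eff.get("batch", 0.0) * (batch - 1)
        + eff.get("carcass_weight", 0.0) * (cw - 90.0)
        + truth.effect_per_copy * (truth.causal_copies_per_sample - 2)
        + polygenic
        + rng.normal(0.0, np.sqrt(sigma_e2), size=n)
    )
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "ear_area": ear,
            "sex": sex,
            "batch": batch,
            "carcass_weight": cw,
        }
    )


def gc_bias(gc: np.ndarray, strength: float = 2.0, optimum: float = 0.45,
            floor: float = 0.1) -> np.ndarray:
    """Unimodal quadratic capture-efficiency curve peaking at ``optimum`` GC."""
    return np.maximum(floor, 1.0 - strength * (np.asarray(gc) - optimum) ** 2)


def _smooth_gc(rng: np.random.Generator, length: int, mean: float = 0.45,
               sd: float = 0.06, window: int = 101) -> np.ndarray:
    """A smooth random GC-fraction track (moving-average of white noise)."""
    raw = rng.normal(0.0, 1.0, size=length + window)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="valid")[:length]
    smooth *= sd / max(smooth.std(), 1e-12)
    return np.clip(mean + smooth, 0.05, 0.95)


def simulate_depth_track(
    region_len: int = 10_000,
    mean_depth: float = 30.0,
    gc_profile: np.ndarray | None = None,
    cnv_interval: tuple[int, int] | None = None,
    copies: int = 2,
    dispersion: float = 0.02,
    seed: int = 0,
    *,
    chrom: str = "5",
    start: int = 1,
    gc_bias_strength: float = 2.0,
) -> DepthTrack:
    """Per-base depth with GC bias and (optionally) a duplicated segment.

    Expected depth is mean_depth * gc_bias(gc) * copies/2 inside the CNV
    interval (1-based inclusive, in track coordinates) and * 1 outside.
    Counts are negative-binomial with var = mu + dispersion * mu^2
    (Poisson as dispersion -> 0).
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    rng = np.random.default_rng(seed)
    if gc_profile is None:
        gc = _smooth_gc(rng, region_len)
    else:
        gc = np.asarray(gc_profile, dtype=float)
        if len(gc) != region_len:
            raise ValueError("gc_profile length must equal region_len")

    mu = mean_depth * gc_bias(gc, strength=gc_bias_strength)
    ratio = np.ones(region_len)
    if cnv_interval is not None:
        a, b = cnv_interval
        if not (1 <= a <= b <= region_len):
            raise ValueError("cnv_interval must lie within the region")
        ratio[a - 1 : b] = copies / 2.0
    mu = mu * ratio

    if dispersion <= 0:
        depth = rng.poisson(mu).astype(float)
    else:
        r = 1.0 / dispersion
        depth = np.where(
            mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12))), 0
        ).astype(float)
    return DepthTrack(chrom=chrom, start=start, depth=depth, gc=gc)


def simulate_ddpcr(copies: float, n_droplets: int = 20_000,
                   ref_lambda: float = 0.5, seed: int = 0) -> DdpcrWell:
    """One ddPCR well: target occupancy scales as ref_lambda * copies / 2."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    if ref_lambda <= 0:
        raise ValueError("ref_lambda must be > 0")
    rng = np.random.default_rng(seed)
    lam_t = ref_lambda * copies / 2.0
    pos_t = int(rng.binomial(n_droplets, 1.0 - np.exp(-lam_t)))
    pos_r = int(rng.binomial(n_droplets, 1.0 - np.exp(-ref_lambda)))
    return DdpcrWell(
        positives_target=pos_t,
        negatives_target=n_droplets - pos_t,
        positives_reference=pos_r,
        negatives_reference=n_droplets - pos_r,
    )


def simulate_qpcr(copies: float, ct_ref_mean: float = 24.0,
                  noise_sd: float = 0.1, replicates: int = 3,
                  seed: int = 0, sample_id: str = "sim") -> QpcrMeasurement:
    """Triplicate Ct values for the comparative-Ct assay.

    One extra copy halves DeltaCt by one cycle: the target Ct mean is
    ct_ref_mean - log2(copies / 2). The calibrator is a two-copy sample, so
    its DeltaCt is 0 by construction.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if copies <= 0:
        raise ValueError("qPCR requires copies > 0 (no target amplification)")
    rng = np.random.default_rng(seed)
    ct_t = ct_ref_mean - np.log2(copies / 2.0) + rng.normal(0, noise_sd, replicates)
    ct_r = ct_ref_mean + rng.normal(0, noise_sd, replicates)
    return QpcrMeasurement(
        sample_id=sample_id,
        ct_target=ct_t,
        ct_reference=ct_r,
        calibrator_delta_ct=0.0,
    )


def simulate_expression(copies: np.ndarray, baseline: float = 1.0,
                        fold_per_copy: float = 1.5, noise_sd: float = 0.25,
                        seed: int = 0,
                        sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Relative expression increasing multiplicatively with copy number.

    Mean expression is baseline * fold_per_copy**(copies - 2); noise is
    log-normal (Gaussian with sd ``noise_sd`` on the log2 scale), keeping the
    2^-DeltaDeltaCt-style values strictly positive.
    """
    copies = np.asarray(copies)
    rng = np.random.default_rng(seed)
    mean = baseline * fold_per_copy ** (copies - 2.0)
    value = mean * 2.0 ** rng.normal(0.0, noise_sd, size=len(copies))
    ids = sample_ids or [f"S{i:04d}" for i in range(len(copies))]
    return pd.DataFrame({"sample_id": ids, "value": value})
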