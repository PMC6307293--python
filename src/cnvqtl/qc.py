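"""SNP and sample quality control.

Filters follow array-genotyping convention: samples with low call rate are
dropped first, then SNP statistics (call rate, minor allele frequency,
Hardy-Weinberg exact P) are recomputed on the retained samples and SNPs
failing any threshold are removed. Boundary values are kept (a SNP at
exactly the MAF threshold passes).

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, the P-value sums the probabilities of every heterozygote
configuration no more probable than the observed one. The exact test is
stable in the far tail where the filter operates, unlike the chi-square
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = ["QcThresholds", "QcReport", "snp_stats", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QcThresholds:
    min_snp_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    min_sample_call_rate: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_maf", "min_hwe_p",
                     "min_sample_call_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    samples_removed_call_rate: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    snps_removed_all_missing: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg P-value.

    Conditions on the observed allele counts and sums the hypergeometric-type
    probabilities of all heterozygote counts whose probability does not
    exceed that of the observed configuration. Monomorphic data (a single
    possible configuration) returns 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-side allele count bookkeeping below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    # log-probability of each admissible het count, conditional on alleles:
    #   P(het) = n! / (nAA! nAa! naa!) * 2^het * nA! na! / (2n)!
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_rare + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_Aa)[0]]
    # tolerance guards ties against floating round-off
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def snp_stats(dosage_column: np.ndarray) -> tuple[float, float, float]:
    """(call_rate, minor allele frequency, exact HWE P) for one SNP column.

    An all-missing column returns (0, nan, nan); callers flag rather than
    crash on it.
    """
    d = np.asarray(dosage_column, dtype=float)
    n = d.size
    obs = d[~np.isnan(d)]
    call_rate = obs.size / n if n else 0.0
    if obs.size == 0:
        return call_rate, float("nan"), float("nan")
    p_alt = obs.sum() / (2 * obs.size)
    maf = min(p_alt, 1.0 - p_alt)
    n_aa = int((obs == 2).sum())
    n_Aa = int((obs == 1).sum())
    n_AA = int((obs == 0).sum())
    return float(call_rate), float(maf), hwe_exact_test(n_AA, n_Aa, n_aa)


def apply_qc(genotypes: GenotypeMatrix,
             thresholds: QcThresholds = QcThresholds()
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Sample call-rate filter, then SNP filters recomputed on kept samples."""
    report = QcReport(
        n_samples_in=genotypes.n_samples,
        n_snps_in=genotypes.n_snps,
    )

    sample_cr = 1.0 - np.isnan(genotypes.dosage).mean(axis=1)
    keep_samples = sample_cr >= thresholds.min_sample_call_rate
    report.samples_removed_call_rate = int((~keep_samples).sum())
    g = genotypes.subset_samples(keep_samples)

    keep = np.ones(g.n_snps, dtype=bool)
    if g.n_samples > 0:
        for j in range(g.n_snps):
            cr, maf, hwe_p = snp_stats(g.dosage[:, j])
            if np.isnan(maf):
                keep[j] = False
                report.snps_removed_all_missing += 1
            elif cr < thresholds.min_snp_call_rate:
                keep[j] = False
                report.snps_removed_call_rate += 1
            elif maf < thresholds.min_maf:
                keep[j] = False
                report.snps_removed_maf += 1
            elif hwe_p < thresholds.min_hwe_p:
                keep[j] = False
                report.snps_removed_hwe += 1
    g = g.subset_snps(keep)

    report.n_samples_out = g.n_samples
    report.n_snps_out = g.n_snps
    return g, report
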