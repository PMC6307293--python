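"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive throughout the package; conversion to
0-based half-open happens only at the BED/bedGraph boundary in :mod:`cnvqtl.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs as alt-allele dosages.

    Dosages are stored as floats in {0, 1, 2, nan}; nan marks a missing call.
    SNP positions must be strictly increasing within each chromosome.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # per-SNP chromosome label (str)
    pos: np.ndarray  # per-SNP 1-based base-pair position (int64)
    dosage: np.ndarray  # (n_samples, n_snps) float

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("chrom/pos length must equal number of SNPs")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosage=self.dosage[idx, :].copy(),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
            dosage=self.dosage[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids)


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic segment."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class AssociationResult:
    """Per-variant association statistics from any scan."""

    variant_id: str
    beta: float
    se: float
    chi2: float
    p: float
    lod: float  # -log10(p)
    flag: str = ""  # e.g. "monomorphic", "collinear"

    @classmethod
    def from_chi2(cls, variant_id: str, beta: float, se: float, chi2: float,
                  flag: str = "") -> "AssociationResult":
        from scipy import stats

        chi2 = max(float(chi2), 0.0)
        p = float(stats.chi2.sf(chi2, df=1))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return cls(variant_id, float(beta), float(se), chi2, p,
                   lod=float(-np.log10(p)), flag=flag)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Association results as a TSV-ready DataFrame with fixed column order."""
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "beta": r.beta,
                "se": r.se,
                "chi2": r.chi2,
                "p": r.p,
                "lod": r.lod,
                "flag": r.flag,
            }
            for r in results
        ],
        columns=["variant_id", "beta", "se", "chi2", "p", "lod", "flag"],
    )


@dataclass
class DepthTrack:
    """Per-base read depth plus GC fraction over one contiguous region."""

    chrom: str
    start: int  # 1-based position of depth[0]
    depth: np.ndarray  # per-base read depth, float
    gc: np.ndarray  # per-base GC fraction of a centred window

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        if self.depth.shape != self.gc.shape:
            raise ValueError("depth and gc must have equal length")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.depth), dtype=np.int64)


@dataclass
class HaplotypeSet:
    """Phased haplotypes (two per sample) over ordered SNPs.

    ``alleles`` is haplotypes x SNPs with values in {0, 1, -1}; -1 marks a
    missing allele. ``labels`` carries a class per haplotype, e.g. carrier /
    control or Q / q.
    """

    haplotype_ids: list[str]
    snp_ids: list[str]
    pos: np.ndarray
    alleles: np.ndarray  # (n_haplotypes, n_snps) int8
    labels: list[str] = field(default_factory=list)
    chrom: str = "chr"

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        h, m = self.alleles.shape
        if h != len(self.haplotype_ids) or m != len(self.snp_ids) or m != len(self.pos):
            raise ValueError("inconsistent haplotype/SNP dimensions")
        if not np.isin(self.alleles, (-1, 0, 1)).all():
            raise ValueError("alleles must be in {0, 1, -1 (missing)}")
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.labels and len(self.labels) != h:
            raise ValueError("one label per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def select(self, mask: np.ndarray) -> "HaplotypeSet":
        idx = np.flatnonzero(np.asarray(mask)) if np.asarray(mask).dtype == bool \
            else np.asarray(mask)
        return HaplotypeSet(
            haplotype_ids=[self.haplotype_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            pos=self.pos.copy(),
            alleles=self.alleles[idx, :].copy(),
            labels=[self.labels[i] for i in idx] if self.labels else [],
            chrom=self.chrom,
        )


@dataclass
class CopyNumberEstimate:
    """Diploid copy number with its measurement provenance."""

    sample_id: str
    copies: float
    method: str  # "qpcr" | "ddpcr" | "depth"
    genotype: str = ""  # "wild" | "het" | "hom" | "loss"

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.method not in ("qpcr", "ddpcr", "depth"):
            raise ValueError(f"unknown method {self.method!r}")
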