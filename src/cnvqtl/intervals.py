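"""Linkage disequilibrium and confidence-interval definition for a QTL peak.

The confidence interval of an association peak is built in two steps:
first the positional span of all SNPs in strong LD (r^2 strictly above a
threshold, default 0.8) with the peak SNP; then, inside that span, the
2-LOD drop-off rule retains SNPs whose LOD (-log10 P) exceeds the peak LOD
minus the drop, and the interval is the positional span of the retained
SNPs. The step-1 region is the min-max span of the qualifying SNPs (not the
SNP set itself), so interior SNPs in weaker LD still participate in step 2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AssociationResult, GenotypeMatrix, Interval

__all__ = ["ld_r2", "ld_matrix", "confidence_interval", "intersect"]


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values are pairwise-deleted; fewer than two complete pairs, or a
    zero-variance vector, leaves r^2 undefined (nan).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need >= 2 complete pairs for LD")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def ld_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise r^2 between all SNPs (nan where undefined)."""
    m = genotypes.n_snps
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            try:
                v = ld_r2(genotypes.dosage[:, i], genotypes.dosage[:, j])
            except ValueError:
                v = float("nan")
            r2[i, j] = r2[j, i] = v
    return pd.DataFrame(r2, index=genotypes.snp_ids, columns=genotypes.snp_ids)


def confidence_interval(
    assoc_results: list[AssociationResult],
    genotypes: GenotypeMatrix,
    peak_id: str,
    r2_min: float = 0.8,
    lod_drop: float = 2.0,
) -> Interval:
    """LD-bounded 2-LOD drop-off confidence interval around a peak SNP.

    Step 1: the positional span of all SNPs with r^2 > r2_min to the peak
    (strict inequality; the peak always qualifies). Step 2: within that
    span, the span of SNPs with lod > peak_lod - lod_drop. The peak SNP is
    always inside the returned interval; if no other SNP passes the LD
    threshold the interval degenerates to the peak position.
    """
    lod_by_id = {r.variant_id: r.lod for r in assoc_results}
    if peak_id not in lod_by_id:
        raise KeyError(f"peak {peak_id!r} absent from association results")
    k = genotypes.snp_index(peak_id)
    chrom = genotypes.chrom[k]
    peak_lod = lod_by_id[peak_id]
    peak_dos = genotypes.dosage[:, k]

    on_chrom = np.flatnonzero(genotypes.chrom == chrom)
    in_ld = []
    for j in on_chrom:
        if j == k:
            in_ld.append(j)
            continue
        try:
            r2 = ld_r2(peak_dos, genotypes.dosage[:, j])
        except ValueError:
            continue
        if np.isfinite(r2) and r2 > r2_min:
            in_ld.append(j)
    span_pos = genotypes.pos[in_ld]
    lo, hi = int(span_pos.min()), int(span_pos.max())
    if len(in_ld) == 1:
        warnings.warn(f"no SNP besides {peak_id} exceeds r^2 {r2_min}; "
                      "interval degenerates to the peak position")
        return Interval(chrom, lo, hi)

    retained = [
        j for j in on_chrom
        if lo <= genotypes.pos[j] <= hi
        and lod_by_id.get(genotypes.snp_ids[j], -np.inf) > peak_lod - lod_drop
    ]
    if k not in retained:
        retained.append(k)
    ci_pos = genotypes.pos[retained]
    return Interval(chrom, int(ci_pos.min()), int(ci_pos.max()))


def intersect(a: Interval, b: Interval) -> Interval | None:
    """Overlap of two intervals, or None when disjoint or on different chromosomes."""
    if a.chrom != b.chrom:
        warnings.warn(f"intersecting intervals on different chromosomes "
                      f"({a.chrom} vs {b.chrom})")
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start > end:
        return None
    return Interval(a.chrom, start, end)
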