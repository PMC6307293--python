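"""Readers and writers for the pipeline's file formats.

Internal coordinates are 1-based inclusive everywhere; BED and bedGraph are
0-based half-open and converted only here. Genotype TSVs carry a two-line
header (SNP ids, then chrom:pos); VCFs are parsed to alt-allele dosages with
pysam and must be biallelic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DepthTrack, GenotypeMatrix, HaplotypeSet, Interval

__all__ = [
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_genotypes_vcf", "write_genotypes_vcf",
    "read_phenotypes", "write_phenotypes",
    "read_depth_bedgraph", "write_depth_bedgraph",
    "write_bed", "read_haplotypes_tsv", "write_haplotypes_tsv",
    "write_json", "read_genotypes",
]

MISSING_TOKEN = "NA"


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(geno.snp_ids) + "\n")
        fh.write("#position\t" + "\t".join(
            f"{c}:{p}" for c, p in zip(geno.chrom, geno.pos)) + "\n")
        for i, sid in enumerate(geno.sample_ids):
            row = [
                MISSING_TOKEN if np.isnan(v) else str(int(v))
                for v in geno.dosage[i]
            ]
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        posline = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id" or not posline[0].startswith("#"):
            raise ValueError(f"{path}: malformed genotype TSV header")
        snp_ids = header[1:]
        chrom, pos = [], []
        for k, tok in enumerate(posline[1:], start=1):
            try:
                c, p = tok.rsplit(":", 1)
                chrom.append(c)
                pos.append(int(p))
            except ValueError:
                raise ValueError(f"{path} line 2 column {k + 1}: bad "
                                 f"chrom:pos token {tok!r}") from None
        sample_ids, rows = [], []
        for ln, line in enumerate(fh, start=3):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(snp_ids) + 1:
                raise ValueError(f"{path} line {ln}: expected "
                                 f"{len(snp_ids) + 1} fields, got {len(fields)}")
            sample_ids.append(fields[0])
            rows.append([np.nan if f == MISSING_TOKEN else float(f)
                         for f in fields[1:]])
    return GenotypeMatrix(sample_ids, snp_ids, np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64), np.array(rows))


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic GT-only VCF (A as reference, G as alternate allele)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in pd.unique(geno.chrom):
        max_pos = int(geno.pos[geno.chrom == c].max())
        header.contigs.add(str(c), length=max_pos + 1_000_000)
    for sid in geno.sample_ids:
        header.add_sample(sid)
    gt_codes = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, vid in enumerate(geno.snp_ids):
            rec = out.new_record(
                contig=str(geno.chrom[j]), start=int(geno.pos[j]) - 1,
                stop=int(geno.pos[j]), alleles=("A", "G"), id=vid,
            )
            for i, sid in enumerate(geno.sample_ids):
                v = geno.dosage[i, j]
                rec.samples[sid]["GT"] = (None, None) if np.isnan(v) \
                    else gt_codes[v]
            out.write(rec)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a biallelic VCF into alt-allele dosages (1-based positions)."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        snp_ids, chrom, pos, cols = [], [], [], []
        for k, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path} record {k} ({rec.chrom}:{rec.pos}): only "
                    "biallelic records are supported"
                )
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chrom.append(rec.chrom)
            pos.append(rec.pos)  # pysam exposes 1-based POS
            col = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(np.nan)
                else:
                    col.append(float(sum(gt)))
            cols.append(col)
    dosage = np.array(cols, dtype=float).T if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, snp_ids, np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64), dosage)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or \
            path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# --------------------------------------------------------------- phenotypes

def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------------- depth

def write_depth_bedgraph(track: DepthTrack, path: str | Path,
                         value: str = "depth") -> None:
    """Per-base track as bedGraph (0-based half-open), run-length compressed."""
    vals = track.depth if value == "depth" else track.gc
    path = Path(path)
    with path.open("w") as fh:
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                g0 = track.start - 1 + run_start  # 1-based -> 0-based
                g1 = track.start - 1 + i
                fh.write(f"{track.chrom}\t{g0}\t{g1}\t{vals[run_start]:g}\n")
                run_start = i


def read_depth_bedgraph(path: str | Path, gc_path: str | Path | None = None,
                        default_gc: float = 0.45) -> DepthTrack:
    """Depth (and optionally GC) bedGraph into a contiguous per-base track."""

    def _read(p: str | Path) -> tuple[str, int, np.ndarray]:
        rows = []
        chrom = None
        with Path(p).open() as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                f = line.split()
                if len(f) < 4:
                    raise ValueError(f"{p} line {ln}: need 4 bedGraph fields")
                if chrom is None:
                    chrom = f[0]
                elif f[0] != chrom:
                    raise ValueError(f"{p} line {ln}: multiple chromosomes "
                                     "in one track are not supported")
                try:
                    rows.append((int(f[1]), int(f[2]), float(f[3])))
                except ValueError:
                    raise ValueError(f"{p} line {ln}: malformed record") from None
        if not rows:
            raise ValueError(f"{p}: empty bedGraph")
        rows.sort()
        lo = rows[0][0]
        hi = max(r[1] for r in rows)
        vals = np.zeros(hi - lo)
        for a, b, v in rows:
            vals[a - lo : b - lo] = v
        return chrom, lo + 1, vals  # 0-based start -> internal 1-based

    chrom, start, depth = _read(path)
    if gc_path is not None:
        gchrom, gstart, gc = _read(gc_path)
        if gchrom != chrom or gstart != start or len(gc) != len(depth):
            raise ValueError("GC track does not align with the depth track")
    else:
        gc = np.full(len(depth), default_gc)
    return DepthTrack(chrom=chrom, start=start, depth=depth, gc=gc)


# --------------------------------------------------------------- intervals

def write_bed(intervals: list[Interval], path: str | Path,
              names: list[str] | None = None) -> None:
    """Intervals to BED: 1-based inclusive -> 0-based half-open."""
    with Path(path).open("w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names else f"region{k + 1}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


# -------------------------------------------------------------- haplotypes

def write_haplotypes_tsv(haps: HaplotypeSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("haplotype_id\tlabel\t" + "\t".join(haps.snp_ids) + "\n")
        fh.write("#position\t.\t" + "\t".join(
            f"{haps.chrom}:{p}" for p in haps.pos) + "\n")
        labels = haps.labels or ["."] * haps.n_haplotypes
        for i, hid in enumerate(haps.haplotype_ids):
            row = [MISSING_TOKEN if a == -1 else str(int(a))
                   for a in haps.alleles[i]]
            fh.write(f"{hid}\t{labels[i]}\t" + "\t".join(row) + "\n")


def read_haplotypes_tsv(path: str | Path) -> HaplotypeSet:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        posline = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["haplotype_id", "label"] or not posline[0].startswith("#"):
            raise ValueError(f"{path}: malformed haplotype TSV header")
        snp_ids = header[2:]
        chrom, pos = None, []
        for tok in posline[2:]:
            c, p = tok.rsplit(":", 1)
            chrom = c
            pos.append(int(p))
        hap_ids, labels, rows = [], [], []
        for ln, line in enumerate(fh, start=3):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(snp_ids) + 2:
                raise ValueError(f"{path} line {ln}: wrong field count")
            hap_ids.append(f[0])
            labels.append(f[1])
            rows.append([-1 if a == MISSING_TOKEN else int(a) for a in f[2:]])
    return HaplotypeSet(hap_ids, snp_ids, np.array(pos, dtype=np.int64),
                        np.array(rows, dtype=np.int8),
                        labels=[] if all(l == "." for l in labels) else labels,
                        chrom=chrom or "chr")


# ------------------------------------------------------------------- misc

def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Interval):
            return {"chrom": o.chrom, "start": o.start, "end": o.end}
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
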