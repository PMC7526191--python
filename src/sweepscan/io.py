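"""Readers and writers for the standard formats the scan touches.

VCF is read through cyvcf2 and written as plain VCF 4.2 text; gene models
come from GFF3 (via gffutils) or BED; population maps are two-column TSV.
All coordinates inside the package are 1-based inclusive — BED converts at
this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    SITE_INFO_FIELDS,
    FormatError,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    HaplotypeMatrix,
    PopulationMap,
)


def read_vcf(path, region: Optional[str] = None) -> GenotypeMatrix:
    """Load a VCF 4.x file into a :class:`GenotypeMatrix`.

    All records are returned; multi-allelic and non-SNP records are carried
    with ``is_biallelic_snp=False`` so downstream filters can remove them
    explicitly.  INFO numerics are parsed where present and NaN elsewhere.

    Parameters
    ----------
    path : str or Path
    region : str, optional
        Restrict to one chromosome label.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as e:
        raise FormatError(f"cannot open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    chroms, poss, refs, alts, bial = [], [], [], [], []
    allele_rows, phased_rows, dp_rows = [], [], []
    info_rows = {k: [] for k in SITE_INFO_FIELDS}
    n = len(samples)
    for var in vcf:
        if region is not None and var.CHROM != region:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(",".join(var.ALT) if var.ALT else ".")
        is_snp = (
            len(var.ALT) == 1
            and len(var.REF) == 1
            and len(var.ALT[0]) == 1
            and var.ALT[0] in "ACGT"
            and var.REF in "ACGT"
        )
        bial.append(is_snp)
        # cyvcf2 genotypes: [allele_a, allele_b, phased] per sample; -1 = missing
        g = np.asarray(var.genotypes, dtype=np.int16)
        if g.shape != (n, 3):
            raise FormatError(
                f"{path}: record {var.CHROM}:{var.POS} has {g.shape[0]} sample "
                f"calls, expected {n}"
            )
        pair = g[:, :2].astype(np.int8)
        pair[pair < 0] = MISSING
        allele_rows.append(pair)
        phased_rows.append(g[:, 2].astype(bool))
        for k in SITE_INFO_FIELDS:
            v = var.INFO.get(k)
            info_rows[k].append(float(v) if v is not None else np.nan)
        dp = var.format("DP")
        if dp is None:
            dp_rows.append(np.full(n, np.nan))
        else:
            d = dp.astype(float).reshape(n)
            d[d < 0] = np.nan
            dp_rows.append(d)

    m = len(poss)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        alleles=(
            np.stack(allele_rows) if m else np.empty((0, n, 2), dtype=np.int8)
        ),
        phased=(
            np.stack(phased_rows) if m else np.empty((0, n), dtype=bool)
        ),
        site_info={k: np.array(v, dtype=float) for k, v in info_rows.items()},
        dp=np.stack(dp_rows) if m else np.empty((0, n)),
        is_biallelic_snp=np.array(bial, dtype=bool),
        sample_ids=samples,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as plain VCF 4.2 text (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.chrom):  # preserve order, unique
            last = g.pos[g.chrom == c].max() if g.n_sites else 0
            fh.write(f"##contig=<ID={c},length={int(last) + 1000}>\n")
        for k in SITE_INFO_FIELDS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for i in range(g.n_sites):
            info = ";".join(
                f"{k}={g.site_info[k][i]:.4g}"
                for k in SITE_INFO_FIELDS
                if k in g.site_info and np.isfinite(g.site_info[k][i])
            )
            cols = [
                str(g.chrom[i]),
                str(int(g.pos[i])),
                ".",
                str(g.ref[i]),
                str(g.alt[i]),
                ".",
                "PASS",
                info or ".",
                "GT:DP",
            ]
            for j in range(g.n_samples):
                a, b = g.alleles[i, j]
                sep = "|" if g.phased[i, j] else "/"
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                d = g.dp[i, j]
                sd = "." if not np.isfinite(d) else str(int(round(d)))
                cols.append(f"{sa}{sep}{sb}:{sd}")
            fh.write("\t".join(cols) + "\n")


def to_haplotypes(g: GenotypeMatrix) -> HaplotypeMatrix:
    """Split phased diploid calls into a 2N-haplotype binary matrix.

    Every retained site must be phased and non-missing in every sample;
    the first offending (site, sample) is named in the error.
    """
    bad_missing = np.argwhere(g.alleles == MISSING)
    if len(bad_missing):
        i, j = bad_missing[0][0], bad_missing[0][1]
        raise ValueError(
            f"missing genotype at {g.chrom[i]}:{g.pos[i]} "
            f"sample {g.sample_ids[j]}: haplotype extraction needs complete calls"
        )
    het = g.alleles[:, :, 0] != g.alleles[:, :, 1]
    unphased = het & ~g.phased  # homozygous calls carry no phase information
    if unphased.any():
        i, j = np.argwhere(unphased)[0]
        raise ValueError(
            f"unphased heterozygous call at {g.chrom[i]}:{g.pos[i]} "
            f"sample {g.sample_ids[j]}: phased input required"
        )
    n = g.n_samples
    alleles = np.empty((2 * n, g.n_sites), dtype=np.int8)
    alleles[0::2, :] = g.alleles[:, :, 0].T
    alleles[1::2, :] = g.alleles[:, :, 1].T
    hap_to_sample = [(s, c) for s in g.sample_ids for c in (0, 1)]
    return HaplotypeMatrix(
        alleles=alleles, hap_to_sample=hap_to_sample, chrom=g.chrom, pos=g.pos
    )


def haplotypes_to_dosage(h: HaplotypeMatrix) -> np.ndarray:
    """Collapse haplotype pairs back to per-sample dosage (sites x samples)."""
    return (h.alleles[0::2, :] + h.alleles[1::2, :]).T.astype(np.int8)


def read_genes(path) -> list:
    """Load gene models from GFF3 or BED, by extension.

    BED half-open 0-based spans are converted to 1-based inclusive; GFF3 is
    already 1-based inclusive and taken as-is.
    """
    p = str(path)
    ext = os.path.splitext(p)[1].lower()
    if ext in (".gff", ".gff3"):
        return _read_gff3(p)
    if ext == ".bed":
        return _read_bed(p)
    raise FormatError(f"unknown gene annotation extension {ext!r} (want .gff3/.gff/.bed)")


def _read_gff3(path) -> list:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneModel(gid, f.seqid, f.start, f.end, f.strand or "."))
    _check_unique_ids(genes, path)
    return genes


def _read_bed(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >=3 columns")
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = row[3] if df.shape[1] >= 4 else f"feature{i + 1}"
        strand = row[5] if df.shape[1] >= 6 else "."
        genes.append(
            GeneModel(str(name), str(row[0]), int(row[1]) + 1, int(row[2]), strand)
        )
    _check_unique_ids(genes, path)
    return genes


def _check_unique_ids(genes, path):
    seen = set()
    for gmodel in genes:
        if gmodel.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {gmodel.gene_id!r}")
        seen.add(gmodel.gene_id)


def read_popmap(path, target: str, reference: str) -> PopulationMap:
    """Two-column TSV (sample, population) -> PopulationMap with roles."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise FormatError(f"{path}: sample {dup!r} assigned more than once")
    return PopulationMap(dict(zip(df["sample"], df["pop"])), target, reference)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in pm.assignments.items():
            fh.write(f"{s}\t{p}\n")


def intervals_to_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED (0-based half-open) with methods in column 4."""
    with open(path, "w") as fh:
        for iv in intervals:
            methods = ",".join(sorted(iv.methods)) or "."
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{methods}\n")


def genes_to_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            fh.write(
                f"{gm.chrom}\tsweepscan\tgene\t{gm.start}\t{gm.end}\t.\t"
                f"{gm.strand}\t.\tID={gm.gene_id}\n"
            )
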