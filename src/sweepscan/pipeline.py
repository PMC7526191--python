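"""End-to-end orchestration of the selective-sweep scan.

Order of operations mirrors the standard resequencing workflow: site hard
filters -> MAF/missingness filter -> sliding windows -> the four statistics
(windowed Weir-Cockerham Fst, pooled heterozygosity Hp, the pi-ratio
contrast, and window-averaged XP-EHH) -> genome-wide Z-transformation and
one-sided P-values -> per-method outlier intervals -> >=2-method consensus
regions -> gene annotation.  LD pruning is applied only on the PCA branch,
not before the scan statistics.

Everything here is deterministic for fixed inputs and configuration; the
only randomness in the package lives in the simulator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import consensus as cns
from . import filters, freq, haplo, io, windows as win
from .model import GenotypeMatrix, HaplotypeMatrix, PopulationMap

#: column with the raw window value per method
RAW_COLUMNS = {"ZFst": "fst", "ZHp": "hp", "piRatio": "pi_ratio", "XPEHH": "xpehh"}


@dataclass
class ScanConfig:
    window_size: int = win.DEFAULT_WINDOW_SIZE
    window_step: int = win.DEFAULT_WINDOW_STEP
    min_snps: int = win.DEFAULT_MIN_SNPS
    fst_weighted: bool = True
    pi_ratio_form: str = "log2"
    ehh_cutoff: float = haplo.EHH_CUTOFF
    ehh_max_extend: int = haplo.MAX_EXTEND
    ehh_max_gap: int = haplo.MAX_GAP
    consensus: cns.ConsensusConfig = field(default_factory=cns.ConsensusConfig)


@dataclass
class ScanResult:
    window_table: pd.DataFrame
    windows: list
    outliers: Dict[str, list]
    regions: list
    gene_records: list
    overlap_counts: pd.DataFrame


def window_statistics(
    g: GenotypeMatrix,
    h: HaplotypeMatrix,
    popmap: PopulationMap,
    chrom_lengths: Dict[str, int],
    cfg: ScanConfig | None = None,
) -> tuple:
    """Compute the per-window table of all four statistics.

    `g` and `h` must describe the same (already filtered) site set; `h`
    may be None to skip XP-EHH (its columns are then absent).
    """
    cfg = cfg or ScanConfig()
    t_idx = g.sample_indices(popmap.target_samples)
    r_idx = g.sample_indices(popmap.reference_samples)

    wlist = win.make_windows(chrom_lengths, cfg.window_size, cfg.window_step)
    win.assign_snps(wlist, g, cfg.min_snps)

    comp = freq.wc_components(g, t_idx, r_idx)
    n_major, n_minor = freq.major_minor_counts(g, t_idx)
    pi_t_sites = freq.pi_sites(g, t_idx)
    pi_r_sites = freq.pi_sites(g, r_idx)

    rows = []
    for w in wlist:
        if w.masked:
            fst = hp = pit = pir = ratio = np.nan
        else:
            fst = freq.fst_window(comp, w, weighted=cfg.fst_weighted)
            hp = freq.hp_window(n_major, n_minor, w)
            pit = freq.pi_window(pi_t_sites, w)
            pir = freq.pi_window(pi_r_sites, w)
            ratio = freq.pi_ratio_window(pir, pit, form=cfg.pi_ratio_form)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": w.n_snps,
                "masked": w.masked,
                "mask_reason": w.mask_reason,
                "fst": fst,
                "hp": hp,
                "pi_target": pit,
                "pi_ref": pir,
                "pi_ratio": ratio,
            }
        )
    table = pd.DataFrame(rows)

    if h is not None:
        site_scores = haplo.xpehh_scan(
            h,
            h.rows_for_samples(popmap.target_samples),
            h.rows_for_samples(popmap.reference_samples),
            cutoff=cfg.ehh_cutoff,
            max_extend=cfg.ehh_max_extend,
            max_gap=cfg.ehh_max_gap,
        )
        _, win_means = haplo.xpehh_normalize_and_window(
            site_scores["xpehh_raw"].to_numpy(), wlist
        )
        table["xpehh"] = win_means
    else:
        site_scores = None

    for method, col in RAW_COLUMNS.items():
        if col not in table.columns:
            continue
        z = freq.z_transform(table[col].to_numpy())
        table[f"z_{method}"] = z
        table[f"p_{method}"] = freq.normal_pvalue(z, tail=freq.METHOD_TAILS[method])

    table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return wlist, table, site_scores


def scan(
    g_raw: GenotypeMatrix,
    popmap: PopulationMap,
    chrom_lengths: Dict[str, int],
    genes: Optional[list] = None,
    filter_cfg: filters.FilterConfig | None = None,
    scan_cfg: ScanConfig | None = None,
    haplotypes: Optional[HaplotypeMatrix] = None,
    apply_hard_filter: bool = True,
):
    """Full scan from a raw genotype matrix to candidate genes.

    Returns (ScanResult, filter report DataFrame, filtered GenotypeMatrix).
    Haplotypes for XP-EHH are extracted from the filtered matrix (phased
    input required) unless a pre-sited HaplotypeMatrix is supplied.
    """
    filter_cfg = filter_cfg or filters.FilterConfig()
    scan_cfg = scan_cfg or ScanConfig()
    if apply_hard_filter:
        g_hard, report = filters.hard_filter(g_raw, filter_cfg)
    else:
        g_hard, report = g_raw, pd.DataFrame(
            {"chrom": g_raw.chrom, "pos": g_raw.pos, "fail_reasons": ""}
        )
    g = filters.maf_missing_filter(
        g_hard, maf_min=filter_cfg.maf_min, max_missing=filter_cfg.max_missing
    )
    if haplotypes is None:
        h = io.to_haplotypes(g)
    else:
        keep = {(c, p) for c, p in zip(g.chrom, g.pos)}
        idx = np.flatnonzero(
            [(c, p) in keep for c, p in zip(haplotypes.chrom, haplotypes.pos)]
        )
        h = HaplotypeMatrix(
            alleles=haplotypes.alleles[:, idx],
            hap_to_sample=haplotypes.hap_to_sample,
            chrom=haplotypes.chrom[idx],
            pos=haplotypes.pos[idx],
        )

    wlist, table, site_scores = window_statistics(
        g, h, popmap, chrom_lengths, scan_cfg
    )
    ccfg = scan_cfg.consensus
    outliers = {
        m: cns.extract_outliers(wlist, table[f"p_{m}"].to_numpy(), m, ccfg)
        for m in RAW_COLUMNS
        if f"p_{m}" in table.columns
    }
    regions = cns.consensus_regions(outliers, ccfg)
    gene_records = cns.annotate_genes(regions, genes or [], table)
    counts = cns.method_overlap_counts(gene_records, methods=sorted(RAW_COLUMNS))
    result = ScanResult(
        window_table=table,
        windows=wlist,
        outliers=outliers,
        regions=regions,
        gene_records=gene_records,
        overlap_counts=counts,
    )
    return result, report, g, site_scores


@dataclass
class PipelineConfig:
    """File-based run configuration (CLI `scan` subcommand)."""

    vcf: str
    popmap: str
    outdir: str
    genes: Optional[str] = None
    target: str = "FZ"
    reference: str = "UY"
    chromosomes: Optional[list] = None  # e.g. an autosome list; default: all
    chrom_lengths: Optional[Dict[str, int]] = None  # default: max position seen
    filter: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fcfg = filters.FilterConfig(**raw.pop("filter", {}))
        sraw = raw.pop("scan", {})
        ccfg = cns.ConsensusConfig(**sraw.pop("consensus", {}))
        scfg = ScanConfig(consensus=ccfg, **sraw)
        return cls(filter=fcfg, scan=scfg, **raw)


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scan(cfg: PipelineConfig) -> dict:
    """File-in, file-out scan.  Returns the dict of output paths.

    Outputs (all sorted by chrom,start with fixed float formatting, so
    reruns are byte-identical): filter_report.tsv, windows.tsv,
    outliers_<method>.bed, consensus_regions.{bed,tsv},
    candidate_genes.tsv, method_overlap.tsv, xpehh_sites.tsv,
    manifest.json.
    """
    for p in (cfg.vcf, cfg.popmap) + ((cfg.genes,) if cfg.genes else ()):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input not found: {p}")
    os.makedirs(cfg.outdir, exist_ok=True)
    g_raw = io.read_vcf(cfg.vcf)
    if cfg.chromosomes is not None:
        wanted = set(cfg.chromosomes)
        g_raw = g_raw.take_sites(
            np.flatnonzero([c in wanted for c in g_raw.chrom])
        )
    popmap = io.read_popmap(cfg.popmap, cfg.target, cfg.reference)
    genes = io.read_genes(cfg.genes) if cfg.genes else []
    chrom_lengths = cfg.chrom_lengths or {
        c: int(g_raw.pos[g_raw.chrom == c].max()) for c in dict.fromkeys(g_raw.chrom)
    }
    result, report, g, site_scores = scan(
        g_raw, popmap, chrom_lengths, genes, cfg.filter, cfg.scan
    )

    paths = {}

    def out(name):
        paths[name] = os.path.join(cfg.outdir, name)
        return paths[name]

    _write_tsv(report, out("filter_report.tsv"))
    _write_tsv(result.window_table, out("windows.tsv"))
    for m, ivs in result.outliers.items():
        io.intervals_to_bed(ivs, out(f"outliers_{m}.bed"))
    io.intervals_to_bed(result.regions, out("consensus_regions.bed"))
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "methods": ",".join(sorted(r.methods)),
                }
                for r in result.regions
            ],
            columns=["chrom", "start", "end", "methods"],
        ),
        out("consensus_regions.tsv"),
    )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene.gene_id,
                    "chrom": r.gene.chrom,
                    "start": r.gene.start,
                    "end": r.gene.end,
                    "methods": ",".join(sorted(r.methods)),
                    **{f"best_p_{m}": p for m, p in sorted(r.best_p.items())},
                }
                for r in result.gene_records
            ],
            columns=["gene_id", "chrom", "start", "end", "methods"]
            + [f"best_p_{m}" for m in sorted(RAW_COLUMNS)],
        ),
        out("candidate_genes.tsv"),
    )
    _write_tsv(result.overlap_counts, out("method_overlap.tsv"))
    if site_scores is not None:
        _write_tsv(site_scores, out("xpehh_sites.tsv"))

    from . import __version__

    manifest = {
        "config": _config_dict(cfg),
        "inputs": {
            p: _sha256(p)
            for p in [cfg.vcf, cfg.popmap] + ([cfg.genes] if cfg.genes else [])
        },
        "versions": {
            "sweepscan": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(paths),
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


def _config_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {
            f.name: _config_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)
        }
    return cfg


def run_reciprocal(cfg: PipelineConfig) -> dict:
    """Run the forward scan, the role-swapped scan, and report the shared
    candidate genes.  Output directories `forward/` and `reciprocal/` plus
    shared_genes.tsv under cfg.outdir."""
    fwd_cfg = dataclasses.replace(cfg, outdir=os.path.join(cfg.outdir, "forward"))
    rev_cfg = dataclasses.replace(
        cfg,
        outdir=os.path.join(cfg.outdir, "reciprocal"),
        target=cfg.reference,
        reference=cfg.target,
    )
    fwd = run_scan(fwd_cfg)
    rev = run_scan(rev_cfg)
    genes_f = pd.read_csv(fwd["candidate_genes.tsv"], sep="\t")
    genes_r = pd.read_csv(rev["candidate_genes.tsv"], sep="\t")
    shared = sorted(set(genes_f["gene_id"]) & set(genes_r["gene_id"]))
    out = os.path.join(cfg.outdir, "shared_genes.tsv")
    pd.DataFrame({"gene_id": shared}).to_csv(out, sep="\t", index=False)
    return {"forward": fwd, "reciprocal": rev, "shared_genes.tsv": out}
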