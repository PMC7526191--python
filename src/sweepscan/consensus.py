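"""From per-method window P-values to consensus sweep regions and genes.

A window is an outlier for a method when its one-sided P-value is below
the threshold (strict <, default 0.005).  Per-method outlier windows are
merged into intervals; base pairs covered by intervals from at least
`min_methods` distinct methods (default 2) form the consensus regions,
which are then merged across gaps under `merge_gap` bp and intersected
with the gene annotation (>= 1 bp overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from .model import GeneModel, GenomicInterval, Window
from .windows import DEFAULT_MERGE_GAP, merge_regions


@dataclass
class ConsensusConfig:
    p_threshold: float = 0.005
    min_methods: int = 2
    merge_gap: int = DEFAULT_MERGE_GAP
    coverage: str = "bp"  # "bp" (base-pair level) or "window" (window identity)

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (1 <= self.min_methods <= 4):
            raise ValueError("min_methods must be in [1, 4]")


@dataclass
class CandidateGeneRecord:
    gene: GeneModel
    methods: frozenset
    regions: list = field(default_factory=list)
    best_p: dict = field(default_factory=dict)  # method -> min p over gene windows


def extract_outliers(
    windows: List[Window],
    pvalues: np.ndarray,
    method: str,
    cfg: ConsensusConfig | None = None,
) -> List[GenomicInterval]:
    """Significant (p < threshold) unmasked windows for one method, merged
    into per-method intervals."""
    cfg = cfg or ConsensusConfig()
    hits = [
        GenomicInterval(w.chrom, w.start, w.end, frozenset([method]))
        for w, p in zip(windows, pvalues)
        if not w.masked and np.isfinite(p) and p < cfg.p_threshold
    ]
    return merge_regions(hits, max_gap=cfg.merge_gap)


def consensus_regions(
    per_method: Dict[str, List[GenomicInterval]],
    cfg: ConsensusConfig | None = None,
) -> List[GenomicInterval]:
    """Loci covered by >= min_methods distinct methods, merged.

    Coverage is resolved at base-pair level: the chromosome is cut at all
    interval breakpoints, each elementary segment collects the set of
    methods covering it, qualifying segments are concatenated and finally
    merged across gaps < merge_gap.
    """
    cfg = cfg or ConsensusConfig()
    by_chrom: Dict[str, list] = {}
    for method, ivs in per_method.items():
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, method))
    segments = []
    for chrom, ivs in sorted(by_chrom.items()):
        cuts = sorted({s for s, _, _ in ivs} | {e + 1 for _, e, _ in ivs})
        for lo, nxt in zip(cuts, cuts[1:]):
            covering = frozenset(m for s, e, m in ivs if s <= lo <= e)
            if len(covering) >= cfg.min_methods:
                segments.append(GenomicInterval(chrom, lo, nxt - 1, covering))
    # adjacent qualifying segments fuse first (gap 0), then the gap rule
    fused = merge_regions(segments, max_gap=1)
    return merge_regions(fused, max_gap=cfg.merge_gap)


def annotate_genes(
    regions: List[GenomicInterval],
    genes: Iterable[GeneModel],
    window_table: pd.DataFrame | None = None,
) -> List[CandidateGeneRecord]:
    """Genes overlapping any candidate region by >= 1 bp.

    Supporting methods are the union over all overlapped regions.  When a
    per-window statistics table (columns chrom, start, end, p_<method>) is
    supplied, each record also carries the best (minimum) P-value per
    supporting method over windows overlapping the gene span.
    Deterministically ordered by (chrom, start, gene_id).
    """
    records = []
    for gene in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
        hit = [
            r
            for r in regions
            if r.chrom == gene.chrom and r.start <= gene.end and gene.start <= r.end
        ]
        if not hit:
            continue
        methods = frozenset().union(*(r.methods for r in hit))
        best_p: dict = {}
        if window_table is not None and len(window_table):
            wt = window_table
            over = wt[
                (wt["chrom"] == gene.chrom)
                & (wt["start"] <= gene.end)
                & (wt["end"] >= gene.start)
            ]
            for m in sorted(methods):
                col = f"p_{m}"
                if col in over.columns and over[col].notna().any():
                    best_p[m] = float(over[col].min())
        records.append(CandidateGeneRecord(gene, methods, hit, best_p))
    return records


def method_overlap_counts(
    records: List[CandidateGeneRecord], methods: Iterable[str] = None
) -> pd.DataFrame:
    """Venn-style summary of candidate genes by supporting-method set.

    One row per non-empty method combination, with both the intersection
    count (genes supported by at least that combination) and the exact
    count (genes supported by exactly that combination), plus a TOTAL row.
    """
    if methods is None:
        methods = sorted(set().union(*(r.methods for r in records))) if records else []
    methods = list(methods)
    rows = []
    sets = [set(r.methods) for r in records]
    for k in range(1, len(methods) + 1):
        for combo in combinations(methods, k):
            cs = set(combo)
            inter = sum(1 for s in sets if cs <= s)
            exact = sum(1 for s in sets if cs == s)
            rows.append(("+".join(combo), k, inter, exact))
    rows.append(("TOTAL", 0, len(records), len(records)))
    return pd.DataFrame(
        rows, columns=["methods", "n_methods", "n_genes_at_least", "n_genes_exactly"]
    )
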