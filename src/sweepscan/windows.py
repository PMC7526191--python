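"""Sliding genomic windows, SNP-to-window assignment, and interval merging.

Windows are anchored at position 1 and advance by `step`; the terminal
windows of a chromosome are truncated at its end rather than dropped, and
windows with too few SNPs are masked (excluded from normalisation and
outlier calls) rather than removed.
"""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from .model import GenomicInterval, GenotypeMatrix, Window

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_WINDOW_STEP = 20_000
DEFAULT_MIN_SNPS = 10
DEFAULT_MERGE_GAP = 50_000


def make_windows(
    chrom_lengths: Dict[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> List[Window]:
    """Sliding windows starting at 1, 1+step, ... per chromosome.

    The last window(s) are truncated at the chromosome end; a window is
    emitted for every start <= chromosome length.
    """
    if not (size >= step > 0):
        raise ValueError("need size >= step > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        for start in range(1, length + 1, step):
            windows.append(Window(chrom, start, min(start + size - 1, length)))
    return windows


def assign_snps(
    windows: List[Window], g: GenotypeMatrix, min_snps: int = DEFAULT_MIN_SNPS
) -> List[Window]:
    """Fill each window's snp_indices (inclusive bounds; overlapping windows
    share SNPs) and mask windows holding fewer than `min_snps` sites."""
    by_chrom = {}
    for c in dict.fromkeys(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        by_chrom[c] = (idx, g.pos[idx])
    for w in windows:
        idx, pos = by_chrom.get(w.chrom, (np.array([], dtype=np.intp), np.array([])))
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        w.snp_indices = idx[lo:hi]
        if w.n_snps < min_snps:
            w.masked = True
            w.mask_reason = f"snps<{min_snps}"
        else:
            w.masked = False
            w.mask_reason = ""
    return windows


def merge_regions(
    intervals: Iterable[GenomicInterval], max_gap: int = DEFAULT_MERGE_GAP
) -> List[GenomicInterval]:
    """Merge same-chromosome intervals separated by fewer than `max_gap`
    intervening bases (gap = next.start - prev.end - 1; strict <).

    Supporting-method sets are unioned.  Idempotent and order-insensitive.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: List[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end - 1 < max_gap:
            prev = out[-1]
            out[-1] = GenomicInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                prev.methods | iv.methods,
            )
        else:
            out.append(iv)
    return out
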