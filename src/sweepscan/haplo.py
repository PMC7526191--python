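"""Haplotype-sharing statistics: EHH curves, integrated haplotype
homozygosity (iHH), and the cross-population XP-EHH score.

EHH between a core site and a boundary is the probability that two
haplotypes drawn at random are identical over the whole span.  Following
the cross-population convention, every haplotype of a population enters
the calculation regardless of its core allele.  iHH is the trapezoidal
area of EHH against physical distance, truncated where EHH first falls
below a cutoff (the terminal trapezoid is kept).  XP-EHH is
ln(iHH_target / iHH_ref): positive values mean longer haplotype
homozygosity — a sweep at or near fixation — in the target population.

Distances are physical base pairs throughout (no genetic map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import HaplotypeMatrix, Window
from .freq import z_transform

EHH_CUTOFF = 0.05
MAX_EXTEND = 1_000_000  # bp each side
MAX_GAP = 200_000       # bp between adjacent markers before truncation


def ehh_at(h: HaplotypeMatrix, core: int, boundary: int) -> float:
    """EHH over the inclusive span between `core` and `boundary`.

    Haplotypes are grouped by their full allele string over the span;
    EHH = Σ_g C(count_g, 2) / C(n, 2).
    """
    n = h.n_haplotypes
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    lo, hi = min(core, boundary), max(core, boundary)
    span = h.alleles[:, lo : hi + 1]
    _, counts = np.unique(span, axis=0, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


@dataclass
class IhhResult:
    area: float
    flags: set = field(default_factory=set)  # subset of {"edge","gap","max_extend"}


def _pair_frac(counts: np.ndarray, n: int) -> float:
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ihh(
    alleles: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
    max_extend: int = MAX_EXTEND,
    max_gap: int = MAX_GAP,
) -> IhhResult:
    """Integrated EHH around `core` (site index), both directions summed.

    Walks marker-by-marker outward, maintaining the haplotype partition
    incrementally.  Integration per direction stops after the first marker
    with EHH < cutoff (terminal trapezoid included), at `max_extend` bp
    (linear interpolation to the cap), at a marker gap > `max_gap` bp
    (truncated, flagged "gap"), or at the chromosome edge (flagged "edge").
    """
    n, m = alleles.shape
    if n < 2:
        raise ValueError("iHH needs at least 2 haplotypes")
    total = 0.0
    flags: set = set()
    core_pos = positions[core]
    for stepdir in (1, -1):
        _, key = np.unique(alleles[:, core], return_inverse=True)
        prev_ehh = _pair_frac(np.bincount(key), n)
        prev_d = 0.0
        j = core
        while True:
            j += stepdir
            if j < 0 or j >= m:
                flags.add("edge")
                break
            d = abs(int(positions[j]) - int(core_pos))
            if d - prev_d > max_gap:
                flags.add("gap")
                break
            _, key = np.unique(key * 2 + alleles[:, j], return_inverse=True)
            cur_ehh = _pair_frac(np.bincount(key), n)
            if d >= max_extend:
                # interpolate EHH at the cap, close the area there
                frac = (max_extend - prev_d) / (d - prev_d) if d > prev_d else 0.0
                ehh_cap = prev_ehh + frac * (cur_ehh - prev_ehh)
                total += (prev_ehh + ehh_cap) / 2.0 * (max_extend - prev_d)
                flags.add("max_extend")
                break
            total += (prev_ehh + cur_ehh) / 2.0 * (d - prev_d)
            if cur_ehh < cutoff:
                break
            prev_ehh, prev_d = cur_ehh, d
            if prev_ehh == 0.0:
                break
    return IhhResult(area=total, flags=flags)


def ihh_from_curve(distances, ehh_values, cutoff: float = EHH_CUTOFF) -> float:
    """Trapezoidal area of an explicit one-sided EHH curve, stopping after
    the first value below `cutoff` (terminal trapezoid included)."""
    area = 0.0
    for (d0, e0), (d1, e1) in zip(
        zip(distances, ehh_values), zip(distances[1:], ehh_values[1:])
    ):
        area += (e0 + e1) / 2.0 * (d1 - d0)
        if e1 < cutoff:
            break
    return area


def xpehh_raw(
    haps_target: np.ndarray,
    haps_ref: np.ndarray,
    positions: np.ndarray,
    core: int,
    **ihh_kwargs,
) -> float:
    """Raw XP-EHH = ln(iHH_target / iHH_ref) at one core site.

    NaN (masked) when either population's iHH is zero.
    """
    it = ihh(haps_target, positions, core, **ihh_kwargs).area
    ir = ihh(haps_ref, positions, core, **ihh_kwargs).area
    if it <= 0 or ir <= 0:
        return np.nan
    return float(np.log(it / ir))


def _mismatch_tables(alleles: np.ndarray):
    """For every haplotype pair, the index of the next/previous mismatching
    site from each site (m marks "no mismatch to the right", -1 to the
    left).  Backbone of the vectorised all-cores iHH scan."""
    n, m = alleles.shape
    iu, ju = np.triu_indices(n, 1)
    diff = alleles[iu] != alleles[ju]  # (npairs, m)
    npairs = diff.shape[0]
    nextmis = np.empty((npairs, m), dtype=np.int32)
    col = np.full(npairs, m, dtype=np.int32)
    for j in range(m - 1, -1, -1):
        col = np.where(diff[:, j], j, col)
        nextmis[:, j] = col
    prevmis = np.empty((npairs, m), dtype=np.int32)
    col = np.full(npairs, -1, dtype=np.int32)
    for j in range(m):
        col = np.where(diff[:, j], j, col)
        prevmis[:, j] = col
    return nextmis, prevmis


def ihh_all_cores(
    alleles: np.ndarray,
    positions: np.ndarray,
    cutoff: float = EHH_CUTOFF,
    max_extend: int = MAX_EXTEND,
    max_gap: int = MAX_GAP,
) -> np.ndarray:
    """iHH at every site, vectorised; equals :func:`ihh` core by core.

    Uses per-pair next/previous-mismatch tables so each core's EHH decay
    curve is a survival count over pair first-mismatch indices.
    """
    n, m = alleles.shape
    if n < 2:
        raise ValueError("iHH needs at least 2 haplotypes")
    nextmis, prevmis = _mismatch_tables(alleles)
    npairs = nextmis.shape[0]
    areas = np.zeros(m)
    pos = positions.astype(np.int64)
    for c in range(m):
        total = 0.0
        for side in (1, -1):
            if side == 1:
                fm = np.sort(nextmis[:, c])
                js = np.arange(c + 1, m)
                # pairs surviving through marker j: fm > j
                surv = npairs - np.searchsorted(fm, js, side="right")
                ehh0 = (npairs - np.searchsorted(fm, c, side="right")) / npairs
                d = (pos[js] - pos[c]).astype(float) if len(js) else np.empty(0)
            else:
                fm = np.sort(prevmis[:, c])
                js = np.arange(c - 1, -1, -1)
                # pairs surviving through marker j (leftward): fm < j
                surv = np.searchsorted(fm, js, side="left")
                ehh0 = np.searchsorted(fm, c, side="left") / npairs
                d = (pos[c] - pos[js]).astype(float) if len(js) else np.empty(0)
            e = surv / npairs
            total += _one_side_area(d, e, ehh0, cutoff, max_extend, max_gap)
        areas[c] = total
    return areas


def _one_side_area(d, e, ehh0, cutoff, max_extend, max_gap):
    """Trapezoid area for one direction's marker distances `d` and EHH
    values `e`, reproducing the stop rules of :func:`ihh` (gap checked
    first, then the max_extend cap with interpolation, then the cutoff
    with its terminal trapezoid)."""
    L = len(d)
    if L == 0:
        return 0.0
    gaps = np.diff(np.concatenate(([0.0], d)))
    k_gap = int(np.argmax(gaps > max_gap)) if (gaps > max_gap).any() else L
    k_ext = int(np.argmax(d >= max_extend)) if (d >= max_extend).any() else L
    k_cut = int(np.argmax(e < cutoff)) if (e < cutoff).any() else L
    k = min(k_gap, k_ext, k_cut)
    dd = np.concatenate(([0.0], d))
    ee = np.concatenate(([ehh0], e))
    if k == L:  # ran off the chromosome
        return float(np.trapezoid(ee, dd))
    if k == k_gap:  # marker k excluded entirely
        return float(np.trapezoid(ee[: k + 1], dd[: k + 1]))
    if k == k_ext:  # interpolate EHH at the cap and close there
        area = float(np.trapezoid(ee[: k + 1], dd[: k + 1]))
        d0, d1 = dd[k], dd[k + 1]
        e0, e1 = ee[k], ee[k + 1]
        frac = (max_extend - d0) / (d1 - d0) if d1 > d0 else 0.0
        ecap = e0 + frac * (e1 - e0)
        return area + (e0 + ecap) / 2.0 * (max_extend - d0)
    # cutoff: terminal trapezoid included
    return float(np.trapezoid(ee[: k + 2], dd[: k + 2]))


def xpehh_scan(
    h: HaplotypeMatrix,
    target_rows: np.ndarray,
    ref_rows: np.ndarray,
    cutoff: float = EHH_CUTOFF,
    max_extend: int = MAX_EXTEND,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Per-site iHH in both populations and the raw XP-EHH score.

    Chromosomes are scanned independently (EHH never crosses a chromosome
    boundary).  Returns a frame with columns chrom, pos, ihh_target,
    ihh_ref, xpehh_raw (NaN where undefined).
    """
    ht = h.alleles[target_rows]
    hr = h.alleles[ref_rows]
    frames = []
    for c in dict.fromkeys(h.chrom):
        idx = np.flatnonzero(h.chrom == c)
        pos = h.pos[idx]
        it = ihh_all_cores(ht[:, idx], pos, cutoff, max_extend, max_gap)
        ir = ihh_all_cores(hr[:, idx], pos, cutoff, max_extend, max_gap)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where((it > 0) & (ir > 0), np.log(it / ir), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": pos.astype(int),
                    "ihh_target": it,
                    "ihh_ref": ir,
                    "xpehh_raw": raw,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def xpehh_normalize_and_window(raw_scores: np.ndarray, windows: list[Window]):
    """Genome-wide z-normalisation of per-site raw XP-EHH, then the window
    statistic = mean of normalised scores of the window's sites.

    Returns (per-site normalised scores, per-window statistic array with
    NaN for masked/empty windows).
    """
    normalized = z_transform(raw_scores)
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        if w.masked or len(w.snp_indices) == 0:
            continue
        vals = normalized[w.snp_indices]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[i] = vals.mean()
    return normalized, out
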