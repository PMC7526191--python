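"""Site-level quality filters: GATK-style hard filters, MAF/missingness,
and LD pruning of the dosage matrix.

Boundary semantics follow the removal conditions as strict inequalities
(a site with QD exactly 2 or FS exactly 60 passes).  A missing INFO
annotation skips that rule for that site rather than failing it, matching
GATK behaviour where e.g. MQRankSum is undefined without heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix


@dataclass
class FilterConfig:
    """Thresholds for site filtering.  Defaults mirror the standard GATK
    hard-filter set plus the usual MAF / missingness / LD-pruning choices."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    depth_low_frac: float = 1.0 / 3.0   # of the genome-wide mean site depth
    depth_high_frac: float = 3.0
    max_missing_rate: float = 0.1
    maf_min: float = 0.05
    max_missing: float = 0.90           # minimum call rate (plink --max-missing)
    ld_window: int = 50                 # variants
    ld_step: int = 5                    # variants
    ld_r2_max: float = 0.2

    def __post_init__(self):
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.ld_step <= 0 or self.ld_window < self.ld_step:
            raise ValueError("need ld_window >= ld_step > 0")


def hard_filter(g: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Apply the hard site filters; keep sites passing ALL rules.

    Rules (removal is strict, so boundary values pass): QD < qd_min,
    FS > fs_max, MQRankSum < mqranksum_min, ReadPosRankSum <
    readposranksum_min, MQ < mq_min, SOR > sor_max, site mean depth outside
    [depth_low_frac*Dbar, depth_high_frac*Dbar] where Dbar is the mean over
    all sites of the per-site mean sample depth, missing rate >
    max_missing_rate, and not a biallelic SNP.

    Returns
    -------
    (GenotypeMatrix, pandas.DataFrame)
        Surviving sites, and a per-site report with a semicolon-joined
        ``fail_reasons`` column (empty for survivors).
    """
    cfg = cfg or FilterConfig()
    n = g.n_sites
    reasons = [[] for _ in range(n)]

    def apply_rule(values, bad_mask_fn, label):
        v = np.asarray(values, dtype=float)
        present = np.isfinite(v)
        bad = np.zeros(n, dtype=bool)
        bad[present] = bad_mask_fn(v[present])
        for i in np.flatnonzero(bad):
            reasons[i].append(label)

    info = g.site_info
    apply_rule(info.get("QD", np.full(n, np.nan)), lambda v: v < cfg.qd_min, "QD")
    apply_rule(info.get("FS", np.full(n, np.nan)), lambda v: v > cfg.fs_max, "FS")
    apply_rule(
        info.get("MQRankSum", np.full(n, np.nan)),
        lambda v: v < cfg.mqranksum_min,
        "MQRankSum",
    )
    apply_rule(
        info.get("ReadPosRankSum", np.full(n, np.nan)),
        lambda v: v < cfg.readposranksum_min,
        "ReadPosRankSum",
    )
    apply_rule(info.get("MQ", np.full(n, np.nan)), lambda v: v < cfg.mq_min, "MQ")
    apply_rule(info.get("SOR", np.full(n, np.nan)), lambda v: v > cfg.sor_max, "SOR")

    # depth: site mean over samples, referenced to the genome-wide mean
    with np.errstate(invalid="ignore"):
        site_depth = np.nanmean(g.dp, axis=1) if n else np.array([])
    finite = np.isfinite(site_depth)
    if finite.any():
        dbar = float(np.mean(site_depth[finite]))
        lo, hi = cfg.depth_low_frac * dbar, cfg.depth_high_frac * dbar
        bad = np.zeros(n, dtype=bool)
        bad[finite] = (site_depth[finite] < lo) | (site_depth[finite] > hi)
        for i in np.flatnonzero(bad):
            reasons[i].append("DP")

    gt = g.gt
    miss_rate = (gt == MISSING).mean(axis=1) if n else np.array([])
    for i in np.flatnonzero(miss_rate > cfg.max_missing_rate):
        reasons[i].append("missing_rate")
    for i in np.flatnonzero(~g.is_biallelic_snp):
        reasons[i].append("not_biallelic_snp")

    keep = np.array([len(r) == 0 for r in reasons], dtype=bool)
    report = pd.DataFrame(
        {
            "chrom": g.chrom,
            "pos": g.pos,
            "fail_reasons": [";".join(r) for r in reasons],
        }
    )
    return g.take_sites(np.flatnonzero(keep)), report


def allele_counts(g: GenotypeMatrix, sample_index=None):
    """(alt allele count, total called alleles) per site, over the given
    samples (default all).  Missing calls are excluded, never counted."""
    gt = g.gt if sample_index is None else g.gt[:, sample_index]
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=1)
    return alt.astype(np.int64), (2 * called.sum(axis=1)).astype(np.int64)


def maf_missing_filter(
    g: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.90
):
    """Keep sites with pooled minor-allele frequency >= maf_min and call
    rate >= max_missing (plink's --maf / --max-missing semantics).

    MAF is computed over non-missing alleles across all samples pooled.
    Sites with zero called alleles are removed (degenerate).
    """
    alt, tot = allele_counts(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    call_rate = (g.gt != MISSING).mean(axis=1) if g.n_sites else np.array([])
    keep = (tot > 0) & (maf >= maf_min) & (call_rate >= max_missing)
    return g.take_sites(np.flatnonzero(keep))


def _pairwise_r2(gt_block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns of a (samples x
    sites) block, pairwise-complete over non-missing samples."""
    m = gt_block.shape[1]
    r2 = np.zeros((m, m))
    missing = gt_block == MISSING
    if not missing.any():
        x = gt_block.astype(float)
        sd = x.std(axis=0)
        ok = sd > 0
        if ok.any():
            c = np.corrcoef(x[:, ok], rowvar=False)
            c = np.atleast_2d(c)
            sub = np.square(c)
            idx = np.flatnonzero(ok)
            r2[np.ix_(idx, idx)] = sub
        np.fill_diagonal(r2, 1.0)
        return r2
    for a in range(m):
        for b in range(a + 1, m):
            both = ~missing[:, a] & ~missing[:, b]
            if both.sum() < 2:
                continue
            xa = gt_block[both, a].astype(float)
            xb = gt_block[both, b].astype(float)
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(
    g: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> GenotypeMatrix:
    """Greedy LD pruning over sliding variant-count windows, per chromosome.

    Within each window of `window` consecutive retained variants, offending
    pairs (r^2 > r2_max) lose their LATER member; windows shift by `step`
    variants and the sweep repeats until no removal occurs, so the result
    is stable under re-application.
    """
    gt_all = g.gt
    keep = np.ones(g.n_sites, dtype=bool)
    for c in dict.fromkeys(g.chrom):
        chrom_idx = np.flatnonzero(g.chrom == c)
        while True:
            removed_any = False
            live = chrom_idx[keep[chrom_idx]]
            if len(live) < 2:
                break
            for w0 in range(0, len(live), step):
                block = live[w0 : w0 + window]
                block = block[keep[block]]  # may have lost members this sweep
                if len(block) < 2:
                    continue
                r2 = _pairwise_r2(gt_all[block].T)
                for a in range(len(block)):
                    if not keep[block[a]]:
                        continue
                    for b in range(a + 1, len(block)):
                        if keep[block[b]] and r2[a, b] > r2_max:
                            keep[block[b]] = False
                            removed_any = True
                if w0 + window >= len(live):
                    break
            if not removed_any:
                break
    return g.take_sites(np.flatnonzero(keep))
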