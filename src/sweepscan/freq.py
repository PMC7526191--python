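"""Allele-frequency window statistics.

Implements the Weir & Cockerham (1984) two-population Fst variance
components (a: among populations, b: among individuals within populations,
c: within individuals), pooled heterozygosity Hp as defined by Rubin et
al. (2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²), per-bp nucleotide diversity π, the
windowed π-ratio contrast, genome-wide Z-transformation, and one-sided
normal P-values.

Directionality of the one-sided tests: ZFst, π-ratio and XP-EHH are
upper-tail (sweeps raise them in the target population); ZHp is lower-tail
(sweeps depress heterozygosity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import MISSING, GenotypeMatrix, Window

#: one-sided tail per method ("upper" or "lower")
METHOD_TAILS = {"ZFst": "upper", "ZHp": "lower", "piRatio": "upper", "XPEHH": "upper"}
METHODS = tuple(METHOD_TAILS)


@dataclass
class SiteVarianceComponents:
    """Per-site WC84 components; `excluded` marks sites that cannot
    contribute (pooled-monomorphic, or a population without called data)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    excluded: np.ndarray

    def per_site_fst(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom != 0, self.a / denom, np.nan)
        f[self.excluded] = np.nan
        return f


def wc_fst_site(n1, n2, p1, p2, h1, h2) -> SiteVarianceComponents:
    """Weir & Cockerham (1984) variance components for two populations.

    Parameters are per-site arrays (or scalars): sample sizes in diploid
    individuals with called genotypes, alt-allele frequencies, and observed
    heterozygote proportions per population.
    """
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    n2 = np.atleast_1d(np.asarray(n2, dtype=float))
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    h1 = np.atleast_1d(np.asarray(h1, dtype=float))
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    r = 2.0
    nbar = (n1 + n2) / r
    excluded = (n1 < 1) | (n2 < 1) | (nbar <= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
    c = hbar / 2
    excluded |= (pbar <= 0) | (pbar >= 1)  # pooled-monomorphic
    excluded |= ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    for arr in (a, b, c):
        arr[excluded] = np.nan
    return SiteVarianceComponents(a=a, b=b, c=c, excluded=excluded)


def population_site_summary(g: GenotypeMatrix, sample_index: np.ndarray):
    """(n called diploids, alt frequency, het proportion) per site for the
    given sample subset; frequency/het are NaN where nothing is called."""
    gt = g.gt[:, sample_index]
    called = gt != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, gt, 0).sum(axis=1)
    het = ((gt == 1) & called).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_components(g: GenotypeMatrix, target_index, ref_index) -> SiteVarianceComponents:
    """Per-site WC84 components straight from a genotype matrix."""
    n1, p1, h1 = population_site_summary(g, target_index)
    n2, p2, h2 = population_site_summary(g, ref_index)
    # a population with zero called individuals excludes the site
    zero = (n1 == 0) | (n2 == 0)
    p1 = np.where(zero, 0.0, p1)
    p2 = np.where(zero, 0.0, p2)
    h1 = np.where(zero, 0.0, h1)
    h2 = np.where(zero, 0.0, h2)
    comp = wc_fst_site(n1, n2, p1, p2, h1, h2)
    comp.excluded |= zero
    for arr in (comp.a, comp.b, comp.c):
        arr[comp.excluded] = np.nan
    return comp


def fst_window(comp: SiteVarianceComponents, window: Window, weighted: bool = True):
    """Windowed Fst over the window's included sites.

    weighted=True gives the ratio-of-sums Σa/Σ(a+b+c) (VCFtools "weighted"
    column); weighted=False averages per-site ratios.  Returns NaN (masked)
    when no usable site or a zero denominator.
    """
    idx = window.snp_indices
    idx = idx[~comp.excluded[idx]] if len(idx) else idx
    if len(idx) == 0:
        return np.nan
    if weighted:
        num = comp.a[idx].sum()
        den = (comp.a[idx] + comp.b[idx] + comp.c[idx]).sum()
        return num / den if den != 0 else np.nan
    persite = comp.per_site_fst()[idx]
    persite = persite[np.isfinite(persite)]
    return persite.mean() if len(persite) else np.nan


def hp_window(n_major: np.ndarray, n_minor: np.ndarray, window: Window):
    """Pooled heterozygosity Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)² over the
    window's sites, from per-site major/minor allele counts (target
    population only).  Range [0, 0.5]; NaN for an empty window."""
    idx = window.snp_indices
    if len(idx) == 0:
        return np.nan
    smaj = float(n_major[idx].sum())
    smin = float(n_minor[idx].sum())
    tot = smaj + smin
    if tot == 0:
        return np.nan
    return 2.0 * smaj * smin / (tot * tot)


def major_minor_counts(g: GenotypeMatrix, sample_index: np.ndarray):
    """Per-site (major, minor) allele counts within one population; the
    major/minor split is by observed counts, not ref/alt labels."""
    alt, tot = _counts(g, sample_index)
    ref = tot - alt
    return np.maximum(ref, alt), np.minimum(ref, alt)


def _counts(g: GenotypeMatrix, sample_index):
    gt = g.gt[:, sample_index]
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=1).astype(np.int64)
    return alt, (2 * called.sum(axis=1)).astype(np.int64)


def pi_sites(g: GenotypeMatrix, sample_index: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2j(n-j)/(n(n-1)) within one
    population (j = alt count, n = called alleles); 0 for monomorphic,
    NaN where fewer than 2 alleles are called."""
    alt, tot = _counts(g, sample_index)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(tot >= 2, 2.0 * alt * (tot - alt) / (tot * (tot - 1.0)), np.nan)
    return v


def pi_window(site_pi: np.ndarray, window: Window) -> float:
    """Window π per bp: sum of per-site values over the window length."""
    length = window.end - window.start + 1
    if length <= 0:
        raise ValueError("window has non-positive length")
    idx = window.snp_indices
    if len(idx) == 0:
        return 0.0
    vals = site_pi[idx]
    return float(np.nansum(vals)) / length


def pi_ratio_window(pi_ref: float, pi_target: float, form: str = "log2") -> float:
    """Contrast of reference π to target π; high = diversity loss in the
    target.  Default log2(π_ref/π_target); 'raw' gives the plain ratio.
    NaN (masked) when π_target is 0 or either input is not finite."""
    if not (np.isfinite(pi_ref) and np.isfinite(pi_target)):
        return np.nan
    if pi_target <= 0 or pi_ref < 0:
        return np.nan
    if form == "log2":
        return float(np.log2(pi_ref / pi_target)) if pi_ref > 0 else np.nan
    if form == "raw":
        return pi_ref / pi_target
    raise ValueError(f"unknown pi-ratio form {form!r}")


def z_transform(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardise to mean 0, sd 1 over finite entries (population sd by
    default).  NaN entries stay NaN.  Degenerate inputs raise."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("z_transform needs at least 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate score distribution (sd = 0)")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def normal_pvalue(z, tail: str = "upper"):
    """One-sided standard-normal P-value; clipped into (0, 1]."""
    z = np.asarray(z, dtype=float)
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "lower":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p if p.shape else float(p)


def critical_z(p: float = 0.005, tail: str = "upper") -> float:
    """The z cut-off whose one-sided tail probability equals `p`
    (e.g. 2.576 at p = 0.005, the usual ZFst/ZHp threshold)."""
    z = stats.norm.isf(p)
    return float(z if tail == "upper" else -z)
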