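"""Principal component analysis of the genotype matrix with Patterson
normalisation (the smartPCA convention): each site is centred by twice the
shrunk allele-frequency estimate and scaled by sqrt(p(1-p)); missing
entries become 0 after centring (mean imputation)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    coordinates: np.ndarray      # samples x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    sites_used: int
    sample_ids: list


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of samples from the (filtered, pruned) dosage matrix.

    The frequency estimate uses the shrinkage p = (1 + Σdosage)/(2 + 2n)
    so near-fixed sites never divide by zero.  Zero-variance sites are
    dropped.  Output is deterministic: each component's largest-magnitude
    loading across samples is made positive.
    """
    gt = g.gt.astype(float).T  # samples x sites
    n_samp, n_sites = gt.shape
    missing = gt == MISSING
    if missing.all(axis=1).any():
        raise ValueError("a sample has no called genotypes")
    called = (~missing).sum(axis=0)
    alt = np.where(missing, 0, gt).sum(axis=0)
    p = (1.0 + alt) / (2.0 + 2.0 * called)
    if n_sites < n_components:
        raise ValueError(f"only {n_sites} sites for {n_components} components")
    keep = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        v = gt[~missing[:, j], j]
        keep[j] = len(v) > 0 and v.std() > 0
    if keep.sum() == 0:
        # e.g. all samples identical: no variance anywhere, scores all zero
        return PcaResult(
            coordinates=np.zeros((n_samp, n_components)),
            eigenvalues=np.zeros(n_components),
            variance_fractions=np.zeros(n_components),
            sites_used=0,
            sample_ids=list(g.sample_ids),
        )
    x = gt[:, keep]
    miss = missing[:, keep]
    pk = p[keep]
    x = (x - 2.0 * pk) / np.sqrt(pk * (1.0 - pk))
    x[miss] = 0.0
    # eigendecomposition of the sample covariance
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    coords = evecs * np.sqrt(evals)
    # sign fix: largest-magnitude score positive per component
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    total = np.clip(np.linalg.eigvalsh(cov), 0, None).sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        coordinates=coords,
        eigenvalues=evals,
        variance_fractions=frac,
        sites_used=int(keep.sum()),
        sample_ids=list(g.sample_ids),
    )
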