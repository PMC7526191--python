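"""Shared fixtures: small genotype matrices built in memory and a scaled-down
simulation configuration for fast property tests (the acceptance tests use
the generator's full default conditions)."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan.model import MISSING, GenotypeMatrix, PopulationMap
from sweepscan.simulate import SimConfig


def make_genotype_matrix(
    gt,
    pos=None,
    chrom="chr1",
    site_info=None,
    dp=None,
    phased=True,
    sample_prefix="S",
):
    """GenotypeMatrix from a (sites x samples) dosage array.

    Dosage 1 becomes the phased pair (0,1); MISSING becomes (.,.).
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    alleles = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
    alleles[gt == 1, 1] = 1
    alleles[gt == 2] = 1
    alleles[gt == MISSING] = MISSING
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        alleles=alleles,
        phased=np.full((n_sites, n_samples), phased),
        site_info=site_info or {},
        dp=dp if dp is not None else np.full((n_sites, n_samples), 10.0),
        is_biallelic_snp=np.ones(n_sites, dtype=bool),
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
    )


def random_two_pop_matrix(rng, n_sites=200, n_target=15, n_ref=12, missing_rate=0.05):
    """Random dosages with missingness plus the matching PopulationMap."""
    n = n_target + n_ref
    p = rng.uniform(0.05, 0.95, size=n_sites)
    gt = rng.binomial(1, p[:, None], size=(n_sites, n)) + rng.binomial(
        1, p[:, None], size=(n_sites, n)
    )
    miss = rng.random((n_sites, n)) < missing_rate
    gt = gt.astype(np.int8)
    gt[miss] = MISSING
    g = make_genotype_matrix(gt)
    pm = PopulationMap(
        {
            **{f"S{i}": "FZ" for i in range(n_target)},
            **{f"S{i}": "UY" for i in range(n_target, n)},
        },
        target="FZ",
        reference="UY",
    )
    return g, pm


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def fast_sim_config():
    """Scaled-down simulation for unit tests (seconds, not minutes)."""
    return SimConfig(
        pop_size=250,
        split_generations=60,
        n_sites=500,
        chrom_length=500_000,
        sweep_position=250_000,
        seed=11,
    )
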