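"""Core in-memory containers for the two-population sweep scan.

Coordinates are 1-based inclusive everywhere inside the package; BED input
and output converts at the boundary.  Missing genotype calls use the
sentinel :data:`MISSING` (-1), which is distinct from every valid allele
dosage and is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing allele call / dosage.  Never a valid value.
MISSING: int = -1

#: INFO annotations carried per site when present in the source VCF.
SITE_INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x diploid samples.

    Attributes
    ----------
    chrom : array of str, shape (n_sites,)
        Chromosome label per site.
    pos : int64 array, shape (n_sites,)
        1-based physical position; strictly increasing within a chromosome.
    ref, alt : arrays of str, shape (n_sites,)
        The two alleles.  For sites flagged non-biallelic, ``alt`` holds the
        comma-joined ALT list; such sites are carried only until filtering.
    alleles : int8 array, shape (n_sites, n_samples, 2)
        Per-call allele pair (0=ref, 1=alt, MISSING).  Order is as given by
        the source; meaningful only where ``phased`` is True.
    phased : bool array, shape (n_sites, n_samples)
        Whether the call was phased ("|" separator).
    site_info : dict of str -> float64 array, shape (n_sites,)
        Numeric INFO annotations (QD, FS, ...); NaN marks "not present",
        which is distinct from any numeric value.
    dp : float64 array, shape (n_sites, n_samples)
        Per-sample read depth; NaN when absent.
    is_biallelic_snp : bool array, shape (n_sites,)
        False flags multi-allelic or non-SNP records (removable, never
        silently recoded).
    sample_ids : list of str
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray
    phased: np.ndarray
    site_info: dict
    dp: np.ndarray
    is_biallelic_snp: np.ndarray
    sample_ids: list

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def gt(self) -> np.ndarray:
        """Alt-allele dosage per site x sample: {0,1,2} or MISSING."""
        a = self.alleles
        dosage = a.sum(axis=2, dtype=np.int16)
        dosage[(a == MISSING).any(axis=2)] = MISSING
        return dosage.astype(np.int8)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            alleles=self.alleles[index],
            phased=self.phased[index],
            site_info={k: v[index] for k, v in self.site_info.items()},
            dp=self.dp[index],
            is_biallelic_snp=self.is_biallelic_snp[index],
            sample_ids=list(self.sample_ids),
        )

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def validate(self) -> None:
        """Assert the container invariants; raises AssertionError on breach."""
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            assert np.all(np.diff(p) > 0), f"positions not strictly increasing on {c}"
        ok = (self.alleles == MISSING) | (self.alleles == 0) | (self.alleles == 1)
        assert ok.all(), "allele values outside {0,1,MISSING}"


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: 2N rows x sites.  No missing entries.

    Rows 2k and 2k+1 are the two chromosome copies of sample k.
    """

    alleles: np.ndarray  # int8, (2N, n_sites), values {0,1}
    hap_to_sample: list  # [(sample_id, copy in {0,1}), ...] per row
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def rows_for_samples(self, ids: Sequence[str]) -> np.ndarray:
        wanted = set(ids)
        return np.array(
            [i for i, (s, _) in enumerate(self.hap_to_sample) if s in wanted],
            dtype=np.intp,
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with target / reference roles."""

    assignments: dict  # sample id -> population label
    target: str
    reference: str

    def __post_init__(self):
        pops = set(self.assignments.values())
        if pops != {self.target, self.reference}:
            raise ValueError(
                f"population map must contain exactly the two populations "
                f"{self.target!r} and {self.reference!r}; found {sorted(pops)}"
            )
        if self.target == self.reference:
            raise ValueError("target and reference populations must differ")

    def samples(self, pop: str) -> list:
        return [s for s, p in self.assignments.items() if p == pop]

    @property
    def target_samples(self) -> list:
        return self.samples(self.target)

    @property
    def reference_samples(self) -> list:
        return self.samples(self.reference)

    def swapped(self) -> "PopulationMap":
        """Roles exchanged (for the reciprocal scan)."""
        return PopulationMap(dict(self.assignments), self.reference, self.target)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class Window:
    """One sliding window, 1-based inclusive bounds."""

    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))
    masked: bool = False
    mask_reason: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    methods: frozenset = frozenset()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start > end")
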