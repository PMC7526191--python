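"""Two-population Wright–Fisher forward simulator with a planted sweep.

The generator stands in for real resequencing data: it produces phased
two-population genotypes with a known selected locus so every scan
statistic can be validated against ground truth.

Model: a fixed set of segregating sites is seeded in an ancestral pool at
linkage equilibrium with frequencies drawn from a 1/x-shaped (neutral-like)
spectrum.  The pool splits into two equal populations that then drift
independently for `split_generations` discrete generations: each child
haplotype is a recombinant copy (Poisson crossovers along the map) of parent
haplotypes sampled with probability proportional to fitness.  Selection is
additive at one sweep site (genotype fitness 1, 1+s/2, 1+s, equivalent to
a per-haplotype weight 1+s/2 per sweep allele), acts in the target
population only from `sweep_onset` generations after the split, and the
sweep allele arises de novo on `sweep_origin_copies` haplotypes at onset
(a hard sweep); attempts where it is lost before sampling are redrawn
(conditioning on establishment) with the retry count recorded.
No other mutation arises after initialisation, which keeps the truth
bookkeeping exact.  All randomness flows from one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numba
import numpy as np

from .model import GeneModel, GenotypeMatrix, HaplotypeMatrix, PopulationMap
from .io import genes_to_gff3, write_popmap, write_vcf


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults emulate the target setting: 15 target + 12 reference diploid
    samples drawn from two recently diverged populations (~0.05 Fst of drift), one
    2 Mb chromosome, and an optional additive sweep in the target
    population.
    """

    n_target: int = 15
    n_ref: int = 12
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    pop_size: int = 3_000          # diploids per population after the split
    split_generations: int = 300
    n_sites: int = 4_000
    recombination_rate: float = 1.25e-6   # per bp per generation (6.25 cM/Mb)
    init_freq_min: float = 0.05        # 1/x spectrum truncation
    init_freq_max: float = 0.95
    sweep_position: int = 1_000_000
    s: float = 0.0                     # selection coefficient (additive)
    sweep_onset: int = 0               # generations after the split
    sweep_origin_copies: int = 1       # haplotypes carrying the new allele
    max_establishment_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.s <= 1):
            raise ValueError("selection coefficient must be in [0, 1]")
        if not (1 <= self.sweep_position <= self.chrom_length):
            raise ValueError("sweep position outside the chromosome")


@dataclass
class SweepTruth:
    """Ground truth of one simulation, recomputable from (config, seed)."""

    sweep_position: int
    sweep_site_index: int
    s: float
    sweep_onset: int
    freq_target_pop: float
    freq_ref_pop: float
    freq_target_sample: float
    freq_ref_sample: float
    seed: int
    n_snps: int
    establishment_retries: int = 0
    notes: dict = field(default_factory=dict)


def _init_frequencies(rng, cfg: SimConfig) -> np.ndarray:
    """Frequencies from a density proportional to 1/x on
    [init_freq_min, init_freq_max] (inverse-CDF sampling)."""
    u = rng.random(cfg.n_sites)
    lo, hi = cfg.init_freq_min, cfg.init_freq_max
    return lo * (hi / lo) ** u


@numba.njit(cache=False)
def _meiosis_kernel(pop, par1, par2, cuts_flat, offsets, out):  # pragma: no cover
    n, m = out.shape
    for i in range(n):
        lo, hi = offsets[i], offsets[i + 1]
        # insertion-sort this child's crossover points
        for t in range(lo + 1, hi):
            v = cuts_flat[t]
            u = t - 1
            while u >= lo and cuts_flat[u] > v:
                cuts_flat[u + 1] = cuts_flat[u]
                u -= 1
            cuts_flat[u + 1] = v
        dst = out[i]
        a = pop[par1[i]]
        b = pop[par2[i]]
        # whole row from parent 1 (vectorises), then overlay the
        # alternating segments inherited from parent 2
        for j in range(m):
            dst[j] = a[j]
        t = lo
        while t < hi:
            c0 = cuts_flat[t]
            c1 = cuts_flat[t + 1] if t + 1 < hi else m
            for j in range(c0, c1):
                dst[j] = b[j]
            t += 2


def _next_generation(rng, pop, weights, map_length, positions):
    """One WF generation: multinomial parent sampling (weighted when
    `weights` is given, uniform otherwise) with a Poisson number of
    crossovers per meiosis (mean `map_length` = rate x chromosome length)
    at uniform physical positions."""
    n, m = pop.shape
    if weights is None:
        par1 = rng.integers(0, n, size=n)
        par2 = rng.integers(0, n, size=n)
    else:
        p = weights / weights.sum()
        par1 = rng.choice(n, size=n, p=p)
        par2 = rng.choice(n, size=n, p=p)
    k = rng.poisson(map_length, size=n)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(k, out=offsets[1:])
    cut_pos = rng.integers(1, positions[-1] + 1, size=int(offsets[-1]))
    cuts_flat = np.searchsorted(positions, cut_pos, side="left").astype(np.int64)
    out = np.empty_like(pop)
    _meiosis_kernel(pop, par1, par2, cuts_flat, offsets, out)
    return out


def simulate_pair(cfg: SimConfig):
    """Run the forward simulation and draw the study sample.

    Returns (HaplotypeMatrix, PopulationMap, SweepTruth).  Bit-identical
    for identical (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_sites, replace=False)) + 1
    freqs = _init_frequencies(rng, cfg)
    sweep_idx = int(np.argmin(np.abs(positions - cfg.sweep_position)))

    nhap = 2 * cfg.pop_size
    map_length = cfg.recombination_rate * cfg.chrom_length
    ancestral = (rng.random((nhap, cfg.n_sites)) < freqs).astype(np.int8)
    if cfg.s > 0:
        # hard sweep: the beneficial allele arises de novo at onset, so it
        # is absent from standing variation (and from the reference pop)
        ancestral[:, sweep_idx] = 0

    pop_r = ancestral
    for _ in range(cfg.split_generations):
        pop_r = _next_generation(rng, pop_r, None, map_length, positions)

    pop_t = ancestral.copy()
    for _ in range(min(cfg.sweep_onset, cfg.split_generations)):
        pop_t = _next_generation(rng, pop_t, None, map_length, positions)
    retries = 0
    if cfg.s > 0 and cfg.sweep_onset < cfg.split_generations:
        base = pop_t
        while True:
            pop_t = base.copy()
            origin = rng.choice(nhap, size=cfg.sweep_origin_copies, replace=False)
            pop_t[origin, sweep_idx] = 1
            lost = False
            for _ in range(cfg.split_generations - cfg.sweep_onset):
                w = 1.0 + (cfg.s / 2.0) * pop_t[:, sweep_idx]
                pop_t = _next_generation(rng, pop_t, w, map_length, positions)
                if not pop_t[:, sweep_idx].any():
                    lost = True
                    break
            if not lost:
                break
            retries += 1
            if retries > cfg.max_establishment_retries:
                raise RuntimeError(
                    f"sweep allele lost in all {retries} attempts; "
                    "raise sweep_origin_copies or s"
                )
    else:
        for _ in range(cfg.split_generations - min(cfg.sweep_onset, cfg.split_generations)):
            pop_t = _next_generation(rng, pop_t, None, map_length, positions)
    pops = {"target": pop_t, "ref": pop_r}

    def draw_sample(pop, n_ind):
        individuals = rng.choice(cfg.pop_size, size=n_ind, replace=False)
        rows = np.empty(2 * n_ind, dtype=np.intp)
        rows[0::2] = 2 * individuals
        rows[1::2] = 2 * individuals + 1
        return pop[rows]

    sample_t = draw_sample(pops["target"], cfg.n_target)
    sample_r = draw_sample(pops["ref"], cfg.n_ref)

    ids_t = [f"FZ{i + 1:02d}" for i in range(cfg.n_target)]
    ids_r = [f"UY{i + 1:02d}" for i in range(cfg.n_ref)]
    # draw_sample keeps rows paired, so rows 2k, 2k+1 belong to sample k
    alleles = np.vstack([sample_t, sample_r])
    hap_to_sample = [(s, c) for s in ids_t + ids_r for c in (0, 1)]
    hmat = HaplotypeMatrix(
        alleles=alleles,
        hap_to_sample=hap_to_sample,
        chrom=np.array([cfg.chrom] * cfg.n_sites, dtype=object),
        pos=positions.astype(np.int64),
    )
    popmap = PopulationMap(
        {**{s: "FZ" for s in ids_t}, **{s: "UY" for s in ids_r}},
        target="FZ",
        reference="UY",
    )
    truth = SweepTruth(
        sweep_position=int(positions[sweep_idx]),
        sweep_site_index=sweep_idx,
        s=cfg.s,
        sweep_onset=cfg.sweep_onset,
        freq_target_pop=float(pops["target"][:, sweep_idx].mean()),
        freq_ref_pop=float(pops["ref"][:, sweep_idx].mean()),
        freq_target_sample=float(sample_t[:, sweep_idx].mean()),
        freq_ref_sample=float(sample_r[:, sweep_idx].mean()),
        seed=cfg.seed,
        n_snps=cfg.n_sites,
        establishment_retries=retries,
        notes={"sweep_origin_copies": cfg.sweep_origin_copies} if cfg.s > 0 else {},
    )
    return hmat, popmap, truth


def to_genotype_matrix(
    h: HaplotypeMatrix,
    site_info: dict | None = None,
    dp: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Package phased haplotypes as a fully-called GenotypeMatrix."""
    n_sites = h.n_sites
    sample_ids = [s for s, c in h.hap_to_sample if c == 0]
    n = len(sample_ids)
    alleles = np.empty((n_sites, n, 2), dtype=np.int8)
    alleles[:, :, 0] = h.alleles[0::2].T
    alleles[:, :, 1] = h.alleles[1::2].T
    return GenotypeMatrix(
        chrom=h.chrom.copy(),
        pos=h.pos.copy(),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        alleles=alleles,
        phased=np.ones((n_sites, n), dtype=bool),
        site_info=site_info if site_info is not None else {},
        dp=dp if dp is not None else np.full((n_sites, n), np.nan),
        is_biallelic_snp=np.ones(n_sites, dtype=bool),
        sample_ids=sample_ids,
    )


_FAIL_DRAWS = {
    "QD": lambda rng: rng.uniform(0.0, 1.9),
    "FS": lambda rng: rng.uniform(61.0, 90.0),
    "MQRankSum": lambda rng: rng.uniform(-20.0, -12.6),
    "ReadPosRankSum": lambda rng: rng.uniform(-15.0, -8.1),
    "MQ": lambda rng: rng.uniform(20.0, 39.5),
    "SOR": lambda rng: rng.uniform(3.1, 6.0),
}


def synthetic_site_annotations(rng, n_sites: int, n_samples: int, fail_sites=None):
    """INFO + depth annotations from labelled passing/failing mixtures.

    `fail_sites` maps site index -> rule name from the hard-filter set;
    those sites receive a value inside the rule's failing range, all other
    values are drawn from comfortably-passing ranges, so the filter truth
    is exact.
    """
    fail_sites = fail_sites or {}
    info = {
        "QD": np.clip(rng.normal(22.0, 6.0, n_sites), 2.5, None),
        "FS": np.clip(rng.exponential(5.0, n_sites), 0.0, 55.0),
        "MQ": np.clip(rng.normal(59.0, 1.0, n_sites), 41.0, 61.0),
        "MQRankSum": np.clip(rng.normal(0.0, 1.5, n_sites), -12.0, 12.0),
        "ReadPosRankSum": np.clip(rng.normal(0.0, 1.5, n_sites), -7.5, 7.5),
        "SOR": np.clip(rng.uniform(0.3, 2.8, n_sites), None, 2.9),
    }
    dp = rng.poisson(10.0, size=(n_sites, n_samples)).astype(float) + 1.0
    for idx, rule in fail_sites.items():
        if rule == "DP_high":
            dp[idx] *= 8.0
        elif rule == "DP_low":
            dp[idx] *= 0.02
        else:
            info[rule][idx] = _FAIL_DRAWS[rule](rng)
    return info, dp


def tile_genes(cfg: SimConfig, width: int = 40_000, spacing: int = 100_000):
    """Gene models tiled along the chromosome plus one centred on the
    sweep site (id 'sweep_target_gene')."""
    genes = []
    half = width // 2
    k = 0
    for centre in range(spacing // 2, cfg.chrom_length, spacing):
        if abs(centre - cfg.sweep_position) < width:
            continue  # leave room for the sweep gene
        k += 1
        genes.append(
            GeneModel(
                f"gene{k:04d}",
                cfg.chrom,
                max(1, centre - half),
                min(cfg.chrom_length, centre + half),
                "+",
            )
        )
    genes.append(
        GeneModel(
            "sweep_target_gene",
            cfg.chrom,
            max(1, cfg.sweep_position - half),
            min(cfg.chrom_length, cfg.sweep_position + half),
            "+",
        )
    )
    return sorted(genes, key=lambda gm: gm.start)


def emit_fixture(
    h: HaplotypeMatrix,
    popmap: PopulationMap,
    truth: SweepTruth,
    cfg: SimConfig,
    outdir,
    fail_fraction: float = 0.06,
):
    """Write the simulated study to disk: phased VCF with synthetic QC
    annotations (a known fraction drawn from failing ranges), population
    map TSV, tiled GFF3 gene models, and the ground truth as JSON.

    Returns a dict of the paths written plus the planted filter-failure
    truth (site position -> violated rule).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng((truth.seed + 777_000_001) % 2**31)
    n_sites = h.n_sites
    rules = list(_FAIL_DRAWS) + ["DP_high", "DP_low"]
    n_fail = int(round(fail_fraction * n_sites))
    candidates = np.setdiff1d(np.arange(n_sites), [truth.sweep_site_index])
    fail_idx = rng.choice(candidates, size=n_fail, replace=False)
    fail_sites = {int(i): rules[int(rng.integers(len(rules)))] for i in fail_idx}
    info, dp = synthetic_site_annotations(
        rng, n_sites, len(popmap.assignments), fail_sites
    )
    g = to_genotype_matrix(h, site_info=info, dp=dp)

    paths = {
        "vcf": os.path.join(outdir, "sim.vcf"),
        "popmap": os.path.join(outdir, "popmap.tsv"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(g, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    genes_to_gff3(tile_genes(cfg), paths["genes"])
    payload = asdict(truth)
    payload["planted_filter_failures"] = {
        str(int(h.pos[i])): rule for i, rule in sorted(fail_sites.items())
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return paths, fail_sites
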