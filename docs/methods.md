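# Methods

`sweepscan` detects recent positive selection in one of two diverged
populations by combining four windowed statistics over phased diploid SNP
genotypes, and validates the whole pipeline end to end against a built-in
forward simulator with a planted sweep. This note records the models, the
parameter choices that matter, and the design decisions taken where more
than one defensible option existed.

## Scan statistics

All four statistics are evaluated in 50 kb sliding windows advanced in
20 kb steps (so consecutive windows share 60% of their span), anchored at
position 1 of each chromosome; terminal windows are truncated at the
chromosome end rather than dropped. Windows holding fewer than `min_snps`
(default 10) SNPs are masked: they are excluded from normalisation,
outlier calling, and the consensus, but remain in the output table with a
mask reason.

**Weir–Cockerham Fst.** Per site the two-population variance components
a (among populations), b (among individuals within populations) and
c (within individuals) are computed from the per-population sample sizes,
allele frequencies and observed heterozygote proportions; sample sizes are
counted per site over non-missing genotypes. A window's value is the
"ratio of sums" Σa / Σ(a+b+c) over its included sites (the weighted form;
a mean-of-per-site-ratios alternative is available via
`ScanConfig.fst_weighted=False`). Pooled-monomorphic sites and sites with
an empty population are excluded from the sums. Negative windowed values
are retained — clamping at zero would distort the null distribution that
the Z-transformation relies on.

**Pooled heterozygosity Hp.** Within the scan's target population only,
each site contributes its major and minor allele counts (major/minor is
decided by the observed counts, never by ref/alt labels), and
Hp = 2·ΣnMAJ·ΣnMIN / (ΣnMAJ + ΣnMIN)² over the window, which lies in
[0, 0.5]. Selection depresses Hp, so its one-sided test uses the lower
tail.

**π and the π-ratio.** Per-population nucleotide diversity uses the
unbiased per-site form 2j(n−j)/(n(n−1)) (j = alternate-allele count among
the n non-missing alleles), summed over window sites and divided by the
window length in bp. The contrast between populations is
log2(π_reference / π_target): positive values mean the target lost
diversity. The logarithmic form makes the ratio distribution symmetric
under the null and turns the "swept in target" signal into the upper
tail; a plain-ratio form is available via `ScanConfig.pi_ratio_form`.
Windows with zero target diversity are masked ("diversity-zero") rather
than mapped to infinity.

**XP-EHH.** EHH between a core site and a boundary is the probability
that two haplotypes drawn without replacement agree at every site in the
inclusive span; all haplotypes of a population participate regardless of
their core allele (the cross-population convention). iHH is the
trapezoidal area of EHH against physical distance, walked marker by
marker outward in both directions until EHH first drops below 0.05 (that
terminal trapezoid is kept), capped at 1 Mb per side (with linear
interpolation to the cap), truncated at inter-marker gaps over 200 kb,
and flagged at chromosome edges. The raw score is
ln(iHH_target / iHH_ref), undefined (masked) when either area is zero.
Distances are physical bp throughout; no genetic map is used. The
production scan uses a vectorised all-cores implementation built on
per-haplotype-pair next/previous-mismatch tables; the test suite holds it
equal to the independent marker-walk implementation and to brute-force
pair enumeration.

## Normalisation, P-values, consensus

Each statistic's raw window values are Z-standardised genome-wide over
unmasked windows (population SD, single bin — no per-chromosome or
frequency-bin stratification), and one-sided normal P-values are taken:
upper tail for ZFst, π-ratio and XP-EHH, lower tail for ZHp. The outlier
cut-off is P < 0.005 (strict), i.e. |Z| > 2.576.

For XP-EHH the reported raw window value is the mean of the genome-wide
site-normalised scores of the window's SNPs. Because a mean of ~100
correlated site scores has standard deviation well below 1, that mean is
then Z-standardised *across windows* like the other three statistics
before the P-value; mapping the window mean directly through the normal
CDF would make the window test far too conservative (its 0.005-tail would
essentially never fire under the null).

Per method, significant windows are merged into intervals. Consensus
regions are the base pairs covered by intervals from at least two
distinct methods (bp-level coverage, resolved by a breakpoint sweep;
window-identity granularity is a config switch), after which regions
separated by fewer than 50,000 intervening bases are merged (strict
less-than; the gap counts the bases strictly between the intervals). A
gene is a candidate when its span overlaps any consensus region by at
least 1 bp, with no promoter/flank extension. No multiple-testing
correction is applied anywhere — the raw P < 0.005 cut-off *is* the
method. The Venn-style summary reports, for every method combination,
both the number of genes supported by at least that combination and by
exactly it.

## Variant filtering

Hard site filters follow the standard GATK short-variant set: QD < 2,
FS > 60, MQRankSum < −12.5, ReadPosRankSum < −8, MQ < 40, SOR > 3 remove
a site; all removal conditions are strict, so a site exactly at a
threshold passes. A missing INFO annotation skips that rule for that site
(rank-sum annotations are undefined without heterozygous calls; failing
such sites would discard valid homozygous-alt records). The depth rule
removes sites whose mean per-sample depth lies outside
[⅓·D̄, 3·D̄], where D̄ is the mean over all sites of the per-site mean
depth — the "mean of the variants containing all individuals" reading.
Sites with > 10% missing calls or that are not biallelic SNPs are also
removed, with every removed site carrying its reason list in the filter
report.

The scan branch then applies minor-allele frequency ≥ 0.05 (computed over
the pooled non-missing alleles of both populations, matching a
single-file filtering step) and call rate ≥ 0.90. LD pruning
(r² > 0.2 within 50-variant windows sliding by 5; the later site of an
offending pair is removed, deterministically) is applied only on the PCA
branch, not before the scan statistics. The pruning sweep repeats until
no removal occurs, so it is stable under re-application; note that pairs
further apart than window − step variants can straddle two anchor
positions and are not guaranteed to be co-examined (the standard variant-
count-window behaviour).

## PCA

Genotypes are Patterson-normalised: each site is centred by 2p̂ and
scaled by √(p̂(1−p̂)) with the shrunk estimate p̂ = (1+Σdosage)/(2+2n),
which never divides by zero at near-fixed sites (and makes duplicated-
sample invariance only approximate). Missing entries become 0 after
centring (mean imputation). Scores come from the eigendecomposition of
the sample covariance matrix; each component's sign is fixed by making
its largest-magnitude score positive, so output is fully deterministic.

## The simulator

The generator emulates the data a two-population resequencing study
feeds into this scan: a target population of 15 and a reference of 12
diploid samples, drawn from two populations that split from a common
ancestral pool and drifted apart, with one optional selected locus in
the target.

Mechanics: a fixed set of segregating sites (default 4000 on 2 Mb) is
seeded in an ancestral pool of 2N haplotypes at linkage equilibrium with
frequencies from a 1/x-shaped spectrum truncated to [0.05, 0.95]. The
pool splits into two populations of N = 3000 diploids that evolve
independently for 300 discrete Wright–Fisher generations; each child
haplotype picks two parents (fitness-weighted multinomially under
selection, uniformly otherwise) and recombines with a Poisson number of
crossovers per meiosis at uniform physical positions. No mutation occurs
after initialisation, so every site's provenance is exact. The final
samples are drawn without replacement. All randomness flows from one
integer seed and output is bit-reproducible.

The sweep is a **hard sweep**: the beneficial allele arises de novo on a
single haplotype at the onset generation (default: at the split) and is
absent from the reference population. Fitness is additive
(1, 1+s/2, 1+s). Runs in which the allele is lost before sampling are
redrawn — loss is detected generation by generation, so failed attempts
are cheap — and the retry count is recorded in the ground truth
(conditioning on establishment). A sweep seeded from standing variation
at linkage equilibrium was rejected: its carriers sit on unrelated
backgrounds, so it fixes the allele without producing the haplotype and
diversity footprint the scan exists to find.

Parameter rationale (units; defaults):

- `pop_size` (diploids; 3000) and `split_generations` (300) jointly set
  the neutral divergence, Fst ≈ T/2N ≈ 0.05 — recently separated
  populations, enough for PCA to separate the samples cleanly.
- `recombination_rate` (per bp per generation; 1.25e-6, i.e. a 2.5 Morgan
  map over 2 Mb or 6.25 cM/Mb) controls how many effectively independent
  genealogies a 50 kb window averages over (≈ 2rT per bp × window ≈ 35–40
  blocks). Much lower values leave so few independent genealogies per
  window that windowed Fst becomes visibly right-skewed and the normal
  0.005-tail over-fires; much higher values shrink the sweep footprint
  below one window. On a real genome the same role is played by deep
  coalescent times rather than a high per-generation rate.
- `s` (0.1 in the sweep experiments): with additive fitness and
  2Ns ≈ 600 the established allele fixes comfortably within 300
  generations, leaving a footprint of roughly 1/(r·T_fix) ≈ 3–10 kb of
  strongly perturbed haplotypes plus a wider diversity shadow — contained
  in, and detectable by, one to three 50 kb windows.
- `n_sites` (4000 over 2 Mb) gives ~80 SNPs per window after the MAF
  filter, comfortably above the 10-SNP mask floor.

What the generator does *not* emulate: new mutation, background
selection, gene conversion, demographic growth or migration, genotyping
error or missingness (the emitted fixture's QC annotations are synthetic
mixtures with exact truth labels, drawn independently of the genotypes),
and reference-genome artefacts. Passing tests therefore demonstrate that
the implementation computes its statistics correctly and that the method
recovers a clean hard sweep under idealised conditions — not that the
P < 0.005 consensus is well calibrated on real resequencing data, where
window scores are known to be heavier-tailed than normal.

## Numerical choices and degenerate inputs

- Missing genotypes use a sentinel (−1) distinct from all dosages and are
  never imputed (except as zero-after-centring inside PCA).
- Z-transformation requires ≥ 2 finite values and a nonzero SD; constant
  score vectors raise a "degenerate score distribution" error rather than
  emitting NaNs.
- P-values are clipped into (0, 1] at the smallest positive float.
- `merge_regions` ties: a gap of exactly the threshold does not merge;
  interval merging is idempotent and order-insensitive after sorting.
- EHH at the core span equals the core-site homozygosity (all haplotypes
  grouped by core allele); a monomorphic core gives EHH = 1.
- Windowed Fst with a zero denominator, empty windows, and π-ratio with
  zero target diversity are masked (NaN), not errors.
- Output tables are sorted by (chrom, start) and written with a fixed
  float format, so identical inputs reproduce byte-identical files; the
  run manifest records input checksums, the full configuration and
  package versions.

## Problem sizes used in validation

The simulation-backed checks run the default conditions above: 20
replicate seeds for the neutral calibration (≈ 2000 windows pooled) and
20 for sweep recovery in the test suite; `scripts/acceptance.py` uses 12
replicates per arm by default (`--n-replicates` raises it). Oracle
equivalence checks use 20 random 200-site fixtures (Weir–Cockerham,
tolerance 1e-10) and 20 random haplotype fixtures (EHH, exact equality).

## Known limitations

- Two populations only; the multi-population Weir–Cockerham estimator,
  iHS/nSL, genetic-map distances and frequency-bin XP-EHH normalisation
  are out of scope.
- Phased, complete genotypes are a precondition for the haplotype
  statistics; the package does not phase.
- The window P-values are descriptive ranks under a normality
  assumption, as in the original method; they are not calibrated
  significance statements for real data.
- The forward simulator's Poisson-crossover, fixed-site model is a
  fixture, not a demographic inference tool.
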