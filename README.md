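# popscan

Selection-scan toolkit for multi-population whole-genome resequencing data.

`popscan` reimplements the analysis core of a livestock/avian-breed
resequencing study as a tested, reusable Python library: starting from a
multi-sample VCF and a sample→population map, it detects selective sweeps
with a joint windowed F_ST × θπ-ratio scan, quantifies inbreeding through
runs of homozygosity (ROH) and F_ROH, measures linkage-disequilibrium
decay, and summarises population structure with neighbor-joining trees and
PCA. Because cohort resequencing data are rarely redistributable, the
package ships a ground-truthed genotype simulator so every stage can be
validated against known answers.

Intended users: population geneticists and breeding researchers analysing
resequenced cohorts of a few populations × a handful of diploid
individuals each, and method developers who need a transparent, fully
seeded reference implementation of these classic scans.

## Methods at a glance

**Differentiation.** Per-locus Weir & Cockerham variance components
(a, b, c) from sample sizes nᵢ, allele frequencies pᵢ and heterozygote
proportions hᵢ; windowed F_ST is the ratio of sums Σa / Σ(a+b+c) over the
loci of each 40-kb window (20-kb step).

**Diversity.** Per-site nucleotide diversity π = 2·c_ref·c_alt/(n(n−1))
summed per window and divided by the window span; the sweep statistic is
log₂(θπ,control / θπ,target), large when the target population has lost
diversity.

**Sweep calls.** Windows in the empirical top 5% of *both* F_ST and the
log₂ ratio (nearest-rank quantiles over usable windows, ties included) are
joint outliers; overlapping or book-ended outlier windows merge into
candidate regions, which are then intersected with gene models.

**ROH / F_ROH.** PLINK-style scanning windows (50 SNPs, ≤2 het, ≤5
missing; hit-rate ≥ 0.05) flag homozygous-state SNPs; maximal flagged runs
(gap ≤ 1000 kb) passing 100 SNPs / 500 kb / ≤50 kb-per-SNP become
segments, and F_ROH = Σ ROH length / autosome length.

**LD.** Two-locus haplotype frequencies for unphased genotypes by EM
(double-heterozygote phase resolved iteratively), r² = D²/(p_A q_A p_B q_B),
averaged in distance bins for pairs ≤ 500 kb apart with MAF ≥ 0.05.

**Structure.** Allele-sharing (IBS) distance d(i,j) = mean |gᵢ−gⱼ|/2,
Saitou–Nei neighbor joining with locus-bootstrap support, and PCA of
variance-normalised genotypes (gᵢⱼ−2pⱼ)/√(2pⱼ(1−pⱼ)).

**Simulator.** Balding–Nichols population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ U(0.05, 0.95), so the
expected F_ST *is* the parameter F; optional founder-mosaic haplotypes for
distance-decaying LD; deterministic sweep and autozygosity injection with
machine-readable truth tables.

## Worked example

`examples/` holds one narrative script per capability. Injecting a sweep
into a simulated background and scanning for it
(`python examples/03_sweep_scan.py`) prints:

```
250 windows scanned, 8 joint outliers
thresholds: F_ST >= 0.3606, log2(pi_control/pi_target) >= 3.1453
  candidate region scaffold_1:2,000,000-2,040,000 (max F_ST 0.361) <- injected sweep
  candidate region scaffold_1:2,100,000-2,160,000 (max F_ST 0.375) <- injected sweep
  candidate region scaffold_1:2,200,000-2,300,000 (max F_ST 0.409) <- injected sweep
  candidate region scaffold_1:2,360,000-2,400,000 (max F_ST 0.378) <- injected sweep
```

All candidate regions fall inside the injected 2.0–2.4 Mb sweep: the
thresholds are the empirical 95th percentiles of the two statistics over
the 250 windows, and only windows extreme in **both** are called. The
other scripts demonstrate simulation + F recovery (the genome-wide
estimate prints 0.0995 against a target F of 0.10), the filter audit
trail, ROH/F_ROH recovery of an injected 600-kb tract, the LD-decay curve
(mean r² 0.067 at 0–50 kb vs 0.044 at 200–500 kb), bootstrap-supported NJ
trees and PCA, gene annotation with Venn overlap counts, and the
end-to-end pipeline.

## Command line

Every stage is also a subcommand of a thin CLI:

```bash
popscan sim --samples-per-pop 8,8 --scaffolds s1:5000000 --target-f 0.1 --seed 1 --out simdir
popscan filter --vcf simdir/simulated.vcf --popmap simdir/simulated.popmap.tsv --out fdir
popscan sweep --vcf ... --popmap ... --target-pop pop1 --control-pop pop2 --out sweepdir
popscan roh / ld / structure / annotate / overlap ...
popscan run --config pipeline.yaml     # everything, with a checksum manifest
```

Re-running `popscan run` with the same config and seed reproduces every
output file byte-for-byte.

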