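# Methods notes

This note records the statistical models, the parameter choices and their
rationale, the behaviour of the synthetic-data generator, and the
numerical conventions the implementation commits to. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Weir–Cockerham F_ST

At a biallelic locus genotyped in r populations with nᵢ diploids,
ALT-allele frequency pᵢ and heterozygote proportion hᵢ:

```
n̄  = Σnᵢ / r
n_c = (r·n̄ − Σnᵢ²/(r·n̄)) / (r−1)
p̄  = Σnᵢpᵢ / (r·n̄)
s²  = Σnᵢ(pᵢ−p̄)² / ((r−1)·n̄)
h̄  = Σnᵢhᵢ / (r·n̄)

a = (n̄/n_c)·[s² − (p̄(1−p̄) − (r−1)/r·s² − h̄/4)/(n̄−1)]
b = (n̄/(n̄−1))·[p̄(1−p̄) − (r−1)/r·s² − (2n̄−1)/(4n̄)·h̄]
c = h̄/2
```

Loci with any ungenotyped population or n̄ ≤ 1 are excluded from window
sums; monomorphic loci contribute a = b = c = 0 and drop out naturally. A
fixed difference between two populations yields F_ST = a/(a+b+c) = 1
exactly; the estimator may be negative around zero differentiation, and
negative window values are deliberately retained in quantile computation
rather than clamped — clamping would bias the outlier thresholds.

Windows combine loci as the **ratio of sums** Σa/Σ(a+b+c) rather than the
mean of per-locus ratios: per-locus ratios are noisy for low-information
loci and the ratio of sums is the standard stable multi-locus combination.

## Windows

Windows are anchored at coordinate 0 of each scaffold, 40 kb wide with a
20-kb step by default, stored 0-based half-open; the final window of a
scaffold is truncated at the scaffold end. Windows with fewer than
`min_snps` (default 10) usable loci, or with a zero F_ST denominator, are
flagged unusable: they enter no quantile and can never be outliers. The
minimum prevents one- or two-SNP windows from dominating the tails of both
statistics.

## Nucleotide diversity and the log₂ ratio

Per-site π uses the unbiased pairwise form 2·c_ref·c_alt/(n(n−1)) with n
the non-missing allele count in the population; sites with n < 2
contribute zero. Window θπ divides the summed site π by the window span
in bp — the denominator convention cancels in the ratio, so the choice
only affects the reported per-bp magnitudes.

log₂(θπ,control/θπ,target) is +∞ when the target has zero diversity in a
window where the control does not; the sentinel ranks above every finite
value (it is the strongest possible sweep signal, not missing data). When
both diversities are zero the ratio carries no information: the value is
NaN and the window is excluded from the ratio quantile and from outlier
candidacy, while still contributing to the F_ST quantile.

## Joint outliers and candidate regions

The top-q tail (default q = 0.05) is defined by the k-th largest value
with k = ⌈q·n⌉ over usable windows (nearest-rank; no interpolation, hence
bit-reproducible), ties at the threshold included. A window must lie in
the top tail of **both** statistics. Outlier windows overlapping or
book-ended on the same scaffold merge into candidate regions. At least 20
usable windows are required — below that an empirical 5% tail is
meaningless and the scan refuses to run.

## ROH detection

The scanning-window algorithm follows the PLINK `--homozyg` design with
the printed defaults: windows of 50 consecutive SNPs pass with ≤ 2
heterozygous and ≤ 5 missing calls; each SNP's hit-rate is the fraction
of passing windows among the windows containing it, flagged at ≥ 0.05
(the upstream tool's default, exposed as a parameter since it is rarely
printed in papers); maximal flagged runs break at inter-SNP gaps > 1000 kb,
are trimmed to their outermost homozygous non-missing calls, and must
contain ≥ 100 SNPs, span ≥ 500 kb and average ≤ 50 kb per SNP.

The behaviour is "PLINK-like", not byte-identical: PLINK's internal het
allowance inside final segments is undocumented, so here heterozygotes
survive inside a segment only insofar as the hit-rate flags allow, and
segments always terminate on a homozygous call. On fixtures with
heterozygote-dense flanks, called boundaries land within one inter-SNP
interval of the true tract (verified in the acceptance tests).

F_ROH = Σ segment length / Σ autosome length. The autosome table is the
caller's responsibility; when scaffolds are not classified, all scaffolds
carrying variants are treated as autosomal (the pipeline does this, with
the simulator's scaffold lengths).

## LD

Two-locus haplotype frequencies from unphased genotypes: all genotype
pairs except double heterozygotes contribute unambiguous haplotype
counts; the double-het mass is split between coupling (AB/ab) and
repulsion (Ab/aB) by EM from a linkage-equilibrium start, iterating until
the observed-data log-likelihood improves by < 1e-10 (max 1000
iterations; the likelihood is non-decreasing by construction and this is
asserted in tests). Pairs with no double heterozygotes are resolved by a
single exact M-step — identical to direct haplotype counting. r² =
D²/(p_A(1−p_A)p_B(1−p_B)) with D = f_AB − p_A·p_B, clipped to [0, 1]
against floating error.

The decay curve enumerates all intra-scaffold pairs within 500 kb with
both MAFs ≥ 0.05, bins by distance (1-kb bins by default; the curve is
insensitive to the width) and pools across scaffolds weighted by pair
counts. The EM is vectorised across pairs with per-pair convergence
tracking, so genome-scale windows are practical.

## Trees and PCA

The allele-sharing distance d(i,j) = mean over shared non-missing loci of
|gᵢ−gⱼ|/2 maps identical genotypes to 0 and opposite homozygotes to 1.
The study tool's distance construction for SNP input is unstated, so this
standard IBS form is a documented design choice, not a replication.

Neighbor joining is the standard Q-matrix agglomeration with a
deterministic lowest-index tie-break; on additive matrices the
reconstruction is exact (and is cross-checked against an independent NJ
implementation in the tests). Negative limb lengths are clamped to zero
with the deficit moved to the sister limb, preserving the pair distance.
Bootstrap support resamples loci with replacement (the standard unit for
distance bootstraps), recomputes distance + NJ, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree.

PCA normalises each polymorphic locus as (g − 2p)/√(2p(1−p)) with p the
sample ALT frequency, imputes missing entries to the column mean (zero
after centering), and takes the SVD. Eigenvalues are those of the sample
covariance of the normalised matrix (full spectrum, descending); sample
scores are U·S with a largest-coordinate-positive sign convention so runs
are reproducible.

## The synthetic-data generator

The generator emulates the structure of a small multi-breed resequencing
cohort — a few populations of 6–8 diploids (configurable), scaffold-based
genome, biallelic SNPs at a chosen density, per-sample depths
Poisson-distributed around a mean of 8 (matching a typical low-coverage
resequencing design) and Phred QUALs ~ N(35, 10) clipped to [0, 60] so
the Q20 filter has something to do.

Differentiation follows Balding–Nichols: ancestral p ~ U(0.05, 0.95),
population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes binomial
in the population frequency. E[F_ST] = F, which makes recovery tests
self-calibrating; acceptance measures |mean windowed F_ST − F| < 0.02 at
F ∈ {0.05, 0.1, 0.2} with 2×50 samples and ~20k SNPs over 20 seeds.
Ancestral frequencies are bounded away from 0/1 so sites are usually
polymorphic, but monomorphic draws are retained to exercise
degenerate-site handling downstream.

LD, when requested (`recomb_rate > 0`), comes from copy-with-
recombination mosaics over 20 founder haplotypes per population: switch
probability 1−exp(−rate·gap) between consecutive SNPs, so nearby loci
share founder identity and r² decays with distance. A rate of 1e-5/bp
gives a ~100-kb correlation length, enough to separate the 0–10-kb and
200–500-kb bins cleanly. The founder bottleneck adds extra drift of order
1/n_founders on top of F, so **F-recovery experiments use recomb_rate = 0**
(site-independent draws); this is a property of the mosaic construction,
not of the estimator. The default is therefore recomb_rate = 0.

`inject_sweep` fixes a fraction `intensity` of the interval's SNPs
(selected evenly spaced, for determinism) at the target population's
majority allele — θπ decreases monotonically in intensity and local F_ST
rises. `inject_roh` copies haplotype 0 over haplotype 1 for one sample in
the interval. Ground truth (target F, sweep intervals, ROH intervals,
per-SNP frequencies) round-trips through TSV tables.

What the generator does **not** emulate: demography (bottlenecks,
migration, admixture), mutation-model realism, sequencing errors in
genotypes, genotype missingness, and coalescent-scale LD structure.
Passing recovery tests therefore show that the estimators measure what
they claim under the stated models — not that the pipeline is robust to
every artefact of real resequencing data.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical checks are stable: F recovery at 2×50
samples × ~20k SNPs × 20 seeds per F value; sweep power on a 5-Mb genome
(~10k SNPs) × 20 seeds; ROH on ~750-SNP scaffolds; LD decay on 1.5-Mb
scaffolds (~600 SNPs, ~90k pairs) × 10 seeds; NJ on 50 random 5–10-taxon
trees; PCA at 2×10 samples × 10 seeds. The estimators themselves are
vectorised and handle genome-scale input (the windowed scan is linear in
SNPs; the LD EM is the heaviest step at ~10 s per 100k pairs).

## Known limitations

- ROH calls are PLINK-like, not PLINK-identical (see above).
- The depth filter's "k-fold the average depth" recipe is ambiguous in
  the literature; it is implemented as a configurable [low, high]
  multiplier window around the genome-wide mean site depth, default
  (1/3, 3), with presets for k = 1, 3, 5.
- The spacing filter's direction is a greedy left-to-right keep-first
  scan — the simplest deterministic rule satisfying "at least 5 bp
  apart".
- Multiallelic records are dropped, not split; splitting belongs upstream
  (`bcftools norm`).
- The top-5% tail is computed over usable windows only; with few usable
  windows the scan refuses to run rather than return unstable thresholds.
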