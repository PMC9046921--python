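"""Ground-truthed multi-population genotype simulator.

The generator stands in for a resequencing cohort (several populations of
6-8 diploid birds each in the motivating study) and is built so that every
downstream stage — filtering, F_ST/pi scans, ROH, LD, trees, PCA — has a
known answer to recover:

* **Differentiation** follows the Balding-Nichols model: each SNP draws an
  ancestral frequency p ~ Uniform(0.05, 0.95); each population then draws
  its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected Weir &
  Cockerham F_ST equals the parameter F.  F = 0 copies the ancestral
  frequency exactly.
* **Linkage disequilibrium** (optional, ``recomb_rate > 0``): haplotypes
  are copy-with-recombination mosaics over a per-population pool of founder
  haplotypes, so nearby loci share founder identity and r^2 decays with
  distance.  The founder bottleneck adds extra drift on top of F (roughly
  1/n_founders), so F-recovery experiments should use ``recomb_rate = 0``
  (site-independent draws).
* **Sweeps** (``inject_sweep``) drive a fraction of the SNPs inside an
  interval to fixation for the target population's majority allele,
  depressing its diversity and inflating local F_ST.
* **Autozygosity** (``inject_roh``) copies one haplotype over the other for
  a sample within an interval, producing a run of homozygosity.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical VCF output.  Ancestral frequencies are bounded away from
0/1 so sites are usually, but not always, polymorphic in the sample —
monomorphic draws are retained to exercise degenerate-site handling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_pops: int = 2
    samples_per_pop: list[int] = field(default_factory=lambda: [8, 8])
    scaffolds: list[tuple[str, int]] = field(default_factory=lambda: [("s1", 5_000_000)])
    snp_density: float = 2e-3          # expected SNPs per bp
    target_F: list[float] | float = 0.1
    recomb_rate: float = 0.0           # per-bp founder-switch probability (0 = no LD)
    n_founders: int = 20               # founder haplotypes per population when recomb_rate > 0
    mean_depth: float = 8.0            # Poisson mean for per-sample DP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop must have n_pops entries")
        if any(s <= 0 for s in self.samples_per_pop):
            raise ValueError("population sizes must be positive")
        if any(ln <= 0 for _, ln in self.scaffolds):
            raise ValueError("scaffold lengths must be positive")
        if isinstance(self.target_F, (int, float)):
            self.target_F = [float(self.target_F)] * self.n_pops
        if len(self.target_F) != self.n_pops:
            raise ValueError("target_F must be scalar or one value per population")
        if any(not 0 <= f < 1 for f in self.target_F):
            raise ValueError("target_F values must lie in [0, 1)")
        if self.recomb_rate < 0 or self.snp_density <= 0:
            raise ValueError("rates must be non-negative (snp_density positive)")

    @property
    def pop_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]


@dataclass
class SimTruth:
    """Generator ground truth; all intervals 0-based half-open."""

    target_F: dict[str, float]
    sweep_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    roh_intervals: list[tuple[str, str, int, int]] = field(default_factory=list)
    ancestral_freqs: pd.DataFrame | None = None  # chrom, pos, p_anc, + per-pop freqs


def simulate_populations(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a multi-population genotype matrix under the Balding-Nichols model."""
    rng = np.random.default_rng(config.seed)
    pops = config.pop_names
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    for pop, size in zip(pops, config.samples_per_pop):
        for k in range(size):
            name = f"{pop}_i{k + 1}"
            samples.append(name)
            pop_of[name] = pop

    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for name, length in config.scaffolds:
        m = rng.binomial(length, min(config.snp_density, 1.0))
        pos = np.sort(rng.choice(length, size=m, replace=False)) + 1  # 1-based
        positions.append(pos)
        chroms.append(np.repeat(name, m))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    chrom_all = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    n_var = pos_all.size

    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    pop_freqs = np.empty((config.n_pops, n_var))
    for k, F in enumerate(config.target_F):
        if F == 0:
            pop_freqs[k] = p_anc
        else:
            scale = (1 - F) / F
            pop_freqs[k] = rng.beta(p_anc * scale, (1 - p_anc) * scale)

    n_samples = len(samples)
    haps = np.empty((2, n_samples, n_var), dtype=np.int8)
    row = 0
    for k, size in enumerate(config.samples_per_pop):
        pf = pop_freqs[k]
        if config.recomb_rate > 0:
            founders = (rng.random((config.n_founders, n_var)) < pf).astype(np.int8)
            scaf_bounds = np.cumsum([0] + [len(p) for p in positions])
            for s in range(size):
                for h in range(2):
                    haps[h, row + s] = _mosaic_haplotype(
                        rng, founders, positions, scaf_bounds, config.recomb_rate
                    )
        else:
            haps[:, row:row + size, :] = (
                rng.random((2, size, n_var)) < pf
            ).astype(np.int8)
        row += size

    dosages = (haps[0] + haps[1]).astype(np.int8)
    depths = rng.poisson(config.mean_depth, size=(n_samples, n_var)).astype(np.int32)
    qual = np.clip(rng.normal(35.0, 10.0, size=n_var), 0.0, 60.0)

    variants = pd.DataFrame({
        "chrom": chrom_all, "pos": pos_all.astype(np.int64),
        "ref": np.repeat("A", n_var), "alt": np.repeat("G", n_var),
        "qual": np.round(qual, 2),
    })
    gm = GenotypeMatrix(
        samples=samples, pops=pop_of, variants=variants, dosages=dosages,
        depths=depths, haplotypes=haps,
        scaffold_lengths={name: ln for name, ln in config.scaffolds},
    )
    freq_table = pd.DataFrame({"chrom": chrom_all, "pos": pos_all, "p_anc": p_anc})
    for k, pop in enumerate(pops):
        freq_table[f"freq_{pop}"] = pop_freqs[k]
    truth = SimTruth(
        target_F={pop: F for pop, F in zip(pops, config.target_F)},
        ancestral_freqs=freq_table,
    )
    return gm, truth


def _mosaic_haplotype(rng, founders, positions, scaf_bounds, recomb_rate):
    """One haplotype as a founder mosaic with per-bp switch probability."""
    n_var = founders.shape[1]
    out = np.empty(n_var, dtype=np.int8)
    for s in range(len(positions)):
        lo, hi = scaf_bounds[s], scaf_bounds[s + 1]
        pos = positions[s]
        if pos.size == 0:
            continue
        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-recomb_rate * gaps)
        switch = rng.random(gaps.size) < p_switch
        founder_ids = np.empty(pos.size, dtype=np.intp)
        founder_ids[0] = rng.integers(founders.shape[0])
        for j in range(1, pos.size):
            founder_ids[j] = (
                rng.integers(founders.shape[0]) if switch[j - 1] else founder_ids[j - 1]
            )
        out[lo:hi] = founders[founder_ids, np.arange(lo, hi)]
    return out


def _interval_variant_index(gm: GenotypeMatrix, scaffold: str, start: int, end: int) -> np.ndarray:
    pos0 = gm.variants["pos"].to_numpy() - 1
    sel = (gm.variants["chrom"].to_numpy() == scaffold) & (pos0 >= start) & (pos0 < end)
    return np.flatnonzero(sel)


def _check_interval(gm: GenotypeMatrix, scaffold: str, start: int, end: int) -> None:
    length = gm.scaffold_length(scaffold)
    if not (0 <= start <= end <= length):
        raise ValueError(f"interval [{start}, {end}) outside scaffold {scaffold} (length {length})")


def inject_sweep(
    gm: GenotypeMatrix,
    truth: SimTruth,
    scaffold: str,
    start: int,
    end: int,
    pop: str,
    intensity: float,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Drive a fraction ``intensity`` of the interval's SNPs to fixation in ``pop``.

    Selected SNPs (evenly spaced through the interval for determinism) are
    fixed for the population's current majority allele, so the population's
    nucleotide diversity over the interval strictly decreases for any
    intensity > 0 (given polymorphic sites) and local differentiation
    rises.  Returns modified copies; the interval is appended to the truth.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("intensity must be in [0, 1]")
    _check_interval(gm, scaffold, start, end)
    idx = _interval_variant_index(gm, scaffold, start, end)
    if idx.size == 0 or start == end:
        warnings.warn(f"sweep interval [{start}, {end}) on {scaffold} contains no SNPs; no-op")
        return gm, truth
    rows = gm.pop_sample_indices(pop)
    gm = gm.copy()
    truth = replace(truth, sweep_intervals=list(truth.sweep_intervals))

    if intensity > 0:
        k = int(round(intensity * idx.size))
        if k > 0:
            chosen = idx[np.unique(np.linspace(0, idx.size - 1, k).round().astype(int))]
            sub = gm.dosages[np.ix_(rows, chosen)]
            called = sub != -1
            alt_frac = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * called.sum(axis=0), 1)
            fixed_allele = (alt_frac >= 0.5).astype(np.int8)  # majority allele
            gm.dosages[np.ix_(rows, chosen)] = 2 * fixed_allele[None, :]
            if gm.haplotypes is not None:
                for h in range(2):
                    gm.haplotypes[h][np.ix_(rows, chosen)] = fixed_allele[None, :]
    truth.sweep_intervals.append((scaffold, int(start), int(end), pop))
    return gm, truth


def inject_roh(
    gm: GenotypeMatrix,
    truth: SimTruth,
    sample: str,
    scaffold: str,
    start: int,
    end: int,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Make ``sample`` autozygous over the interval by copying haplotype 0
    over haplotype 1 (heterozygous dosages collapse to a homozygous call).

    Overlapping intervals for the same sample/scaffold are merged in the
    truth; a zero-length interval is a no-op.
    """
    _check_interval(gm, scaffold, start, end)
    if start == end:
        return gm, truth
    si = gm.sample_index(sample)
    idx = _interval_variant_index(gm, scaffold, start, end)
    gm = gm.copy()
    truth = replace(truth, roh_intervals=list(truth.roh_intervals))
    if idx.size:
        if gm.haplotypes is not None:
            gm.haplotypes[1, si, idx] = gm.haplotypes[0, si, idx]
            gm.dosages[si, idx] = gm.haplotypes[0, si, idx] * 2
        else:
            het = gm.dosages[si, idx] == 1
            gm.dosages[si, idx[het]] = 0

    new = (sample, scaffold, int(start), int(end))
    remaining = list(truth.roh_intervals)
    changed = True
    while changed:  # chained overlaps collapse into one truth interval
        changed = False
        still: list[tuple[str, str, int, int]] = []
        for iv in remaining:
            if iv[0] == sample and iv[1] == scaffold and iv[2] <= new[3] and new[2] <= iv[3]:
                new = (sample, scaffold, min(iv[2], new[2]), max(iv[3], new[3]))
                changed = True
            else:
                still.append(iv)
        remaining = still
    truth.roh_intervals = sorted(remaining + [new])
    return gm, truth


# ---------------------------------------------------------------------------
# truth serialisation
# ---------------------------------------------------------------------------

_SWEEP_COLS = ["scaffold", "start", "end", "pop"]
_ROH_COLS = ["sample", "scaffold", "start", "end"]


def write_truth(truth: SimTruth, directory: str | Path) -> None:
    """Write tab-separated truth tables (lossless round trip via ``read_truth``)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(p, f) for p, f in truth.target_F.items()], columns=["pop", "target_F"]
    ).to_csv(d / "target_f.tsv", sep="\t", index=False)
    pd.DataFrame(truth.sweep_intervals, columns=_SWEEP_COLS).to_csv(
        d / "sweeps.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.roh_intervals, columns=_ROH_COLS).to_csv(
        d / "roh.tsv", sep="\t", index=False
    )
    if truth.ancestral_freqs is not None:
        truth.ancestral_freqs.to_csv(
            d / "ancestral_freqs.tsv", sep="\t", index=False, float_format="%.17g"
        )


def read_truth(directory: str | Path) -> SimTruth:
    d = Path(directory)
    tf = pd.read_csv(d / "target_f.tsv", sep="\t")
    sweeps = pd.read_csv(d / "sweeps.tsv", sep="\t")
    roh = pd.read_csv(d / "roh.tsv", sep="\t")
    freq_path = d / "ancestral_freqs.tsv"
    freqs = pd.read_csv(freq_path, sep="\t") if freq_path.exists() else None
    return SimTruth(
        target_F={str(p): float(f) for p, f in zip(tf["pop"], tf["target_F"])},
        sweep_intervals=[
            (str(r.scaffold), int(r.start), int(r.end), str(r.pop))
            for r in sweeps.itertuples(index=False)
        ],
        roh_intervals=[
            (str(r.sample), str(r.scaffold), int(r.start), int(r.end))
            for r in roh.itertuples(index=False)
        ],
        ancestral_freqs=freqs,
    )
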