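"""Pairwise linkage disequilibrium (r^2) from unphased genotypes and the
distance-binned LD-decay curve.

For two biallelic loci the 3x3 genotype table determines the four haplotype
counts exactly, except for double heterozygotes, whose two phase resolutions
(coupling AB/ab vs repulsion Ab/aB) are disentangled with an EM algorithm:
starting from linkage-equilibrium haplotype frequencies, the E-step splits
double-het individuals between the two resolutions in proportion to
``f_AB*f_ab`` vs ``f_Ab*f_aB``, and the M-step re-estimates the frequencies
from the expected counts.  Iteration stops when the observed-data
log-likelihood improves by less than 1e-10 (or after 1000 iterations).
When the table contains no double heterozygotes, direct haplotype counting
is exact and the EM shortcut is skipped.

From converged frequencies, ``D = f_AB - p_A * p_B`` and
``r^2 = D^2 / (p_A (1-p_A) p_B (1-p_B))``.

The decay curve averages r^2 for all intra-scaffold pairs within a maximum
distance (500 kb by default, both loci passing a minor-allele-frequency
filter, 0.05 by default) in distance bins, pooled across scaffolds with
pair-count weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

EM_TOL = 1e-10
EM_MAX_ITER = 1000
_EPS = 1e-300


def _pair_genotype_counts(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """9-vector of genotype-pair counts n[i*3+j] for one locus pair,
    excluding individuals missing at either locus."""
    ok = (da != MISSING) & (db != MISSING)
    counts = np.zeros(9, dtype=np.int64)
    joint = da[ok] * 3 + db[ok]
    for v, c in zip(*np.unique(joint, return_counts=True)):
        counts[v] = c
    return counts


def em_haplotype_freqs(counts: np.ndarray, return_trace: bool = False):
    """Two-locus haplotype frequencies (f00, f01, f10, f11) by EM.

    ``counts`` is an array of shape (..., 9): genotype-pair counts with the
    first locus's dosage major.  Index ``fxy``: x = ALT count at locus A in
    the haplotype (0/1), y likewise at locus B.  Vectorised over leading
    dimensions.  Returns frequencies of shape (..., 4); with
    ``return_trace=True`` also the per-iteration log-likelihoods of the last
    EM pass (for monotonicity checks; only meaningful for a single pair).
    """
    c = np.asarray(counts, dtype=float)
    n = c.reshape(-1, 9)
    # unambiguous haplotype counts contributed by each genotype cell
    # cells indexed (gA, gB) flattened as gA*3+gB
    k00 = 2 * n[:, 0] + n[:, 1] + n[:, 3]
    k01 = 2 * n[:, 2] + n[:, 1] + n[:, 5]
    k10 = 2 * n[:, 6] + n[:, 3] + n[:, 7]
    k11 = 2 * n[:, 8] + n[:, 7] + n[:, 5]
    ndh = n[:, 4]
    tot = k00 + k01 + k10 + k11 + 2 * ndh  # total haplotypes

    if np.any(tot == 0):
        raise ValueError("no genotyped individuals for some pair")

    # allele frequencies (fixed by the data, invariant under EM)
    pa = (k10 + k11 + ndh) / tot
    pb = (k01 + k11 + ndh) / tot
    # linkage-equilibrium initialisation
    f = np.stack([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb], axis=1)

    def loglik(f):
        f0, f1, f2, f3 = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
        g = np.empty_like(n)
        g[:, 0] = f0 * f0
        g[:, 1] = 2 * f0 * f1
        g[:, 2] = f1 * f1
        g[:, 3] = 2 * f0 * f2
        g[:, 4] = 2 * (f0 * f3 + f1 * f2)
        g[:, 5] = 2 * f1 * f3
        g[:, 6] = f2 * f2
        g[:, 7] = 2 * f2 * f3
        g[:, 8] = f3 * f3
        return (n * np.log(g + _EPS)).sum(axis=1)

    def loglik_subset(f_sub, n_sub):
        f0, f1, f2, f3 = f_sub[:, 0], f_sub[:, 1], f_sub[:, 2], f_sub[:, 3]
        g = np.empty_like(n_sub)
        g[:, 0] = f0 * f0
        g[:, 1] = 2 * f0 * f1
        g[:, 2] = f1 * f1
        g[:, 3] = 2 * f0 * f2
        g[:, 4] = 2 * (f0 * f3 + f1 * f2)
        g[:, 5] = 2 * f1 * f3
        g[:, 6] = f2 * f2
        g[:, 7] = 2 * f2 * f3
        g[:, 8] = f3 * f3
        return (n_sub * np.log(g + _EPS)).sum(axis=1)

    ll = loglik(f)
    trace = [ll.copy()]
    # pairs without double heterozygotes are phase-unambiguous: one M-step
    # from the known counts is exact, so only ambiguous pairs iterate
    active_idx = np.flatnonzero(ndh > 0)
    direct = ndh == 0
    if direct.any():
        f[direct] = np.stack([k00[direct], k01[direct], k10[direct], k11[direct]],
                             axis=1) / tot[direct, None]
        ll = loglik(f)
        trace = [ll.copy()]
    for _ in range(EM_MAX_ITER):
        if active_idx.size == 0:
            break
        fa = f[active_idx]
        coup = fa[:, 0] * fa[:, 3]
        rep = fa[:, 1] * fa[:, 2]
        denom = coup + rep
        w = np.where(denom > 0, coup / np.where(denom > 0, denom, 1.0), 0.5)
        nd = ndh[active_idx]
        e = np.stack([k00[active_idx] + nd * w, k01[active_idx] + nd * (1 - w),
                      k10[active_idx] + nd * (1 - w), k11[active_idx] + nd * w], axis=1)
        f[active_idx] = e / tot[active_idx, None]
        ll_new_sub = loglik_subset(f[active_idx], n[active_idx])
        improved = ll_new_sub - ll[active_idx]
        ll[active_idx] = ll_new_sub
        trace.append(ll.copy())
        active_idx = active_idx[improved > EM_TOL]

    f = f.reshape(np.asarray(counts).shape[:-1] + (4,))
    if return_trace:
        return f, np.stack(trace, axis=-1)
    return f


def r2_from_freqs(f: np.ndarray) -> np.ndarray:
    """r^2 from haplotype frequencies; NaN where either locus is monomorphic."""
    pa = f[..., 2] + f[..., 3]
    pb = f[..., 1] + f[..., 3]
    d = f[..., 3] - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = d * d / denom
    return np.where(denom > 0, np.clip(r2, 0.0, 1.0), np.nan)


@dataclass
class LDPair:
    scaffold: str
    pos_a: int
    pos_b: int
    r2: float
    method: str  # "EM" | "direct"

    @property
    def distance(self) -> int:
        return abs(self.pos_b - self.pos_a)


def pair_r2(gm: GenotypeMatrix, pop: str, locus_a: int, locus_b: int) -> LDPair:
    """r^2 between two variant columns within one population.

    Raises ``ValueError`` if either locus is monomorphic among the
    population's genotyped samples.
    """
    rows = gm.pop_sample_indices(pop)
    da = gm.dosages[rows, locus_a]
    db = gm.dosages[rows, locus_b]
    counts = _pair_genotype_counts(da, db)
    method = "direct" if counts[4] == 0 else "EM"
    f = em_haplotype_freqs(counts)
    r2 = float(r2_from_freqs(f))
    if np.isnan(r2):
        raise ValueError("monomorphic locus in pair; r^2 undefined")
    chrom = gm.variants["chrom"].iloc[locus_a]
    return LDPair(
        scaffold=str(chrom),
        pos_a=int(gm.variants["pos"].iloc[locus_a]),
        pos_b=int(gm.variants["pos"].iloc[locus_b]),
        r2=r2, method=method,
    )


def _pair_counts_block(D: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Genotype-pair count table, shape (n_pairs, 9), for pair index arrays."""
    ind = [(D == k).astype(np.float32) for k in (0, 1, 2)]
    out = np.empty((ia.size, 9), dtype=np.float64)
    for i in range(3):
        a = ind[i][:, ia]
        for j in range(3):
            out[:, i * 3 + j] = np.einsum("sp,sp->p", a, ind[j][:, ib])
    return out


def decay_curve(
    gm: GenotypeMatrix,
    pop: str,
    max_window: int = 500_000,
    min_maf: float = 0.05,
    bin_bp: int = 1_000,
    block_pairs: int = 200_000,
) -> pd.DataFrame:
    """Distance-binned mean r^2 within ``pop``.

    All intra-scaffold locus pairs at distance <= ``max_window`` with both
    minor-allele frequencies >= ``min_maf`` enter; pairs are pooled across
    scaffolds weighted by pair counts.  Returns a DataFrame with columns
    ``bin_start, bin_end, mean_r2, n_pairs`` (empty, with a warning, when no
    pair qualifies).
    """
    rows = gm.pop_sample_indices(pop)
    D = gm.dosages[rows]
    called = D != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, D, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
    maf = np.minimum(p, 1 - p)
    ok_locus = (n_alleles > 0) & (maf >= min_maf)

    n_bins = int(np.ceil(max_window / bin_bp))
    sum_r2 = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)

    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    for chrom in gm.scaffolds():
        idx = np.flatnonzero((chrom_arr == chrom) & ok_locus)
        if idx.size < 2:
            continue
        pos = pos_arr[idx]
        # enumerate pairs (i, j), i < j, pos[j] - pos[i] <= max_window
        hi = np.searchsorted(pos, pos + max_window, side="right")
        counts = hi - np.arange(idx.size) - 1
        ia = np.repeat(np.arange(idx.size), counts)
        ib = np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi) if h > i + 1]) \
            if counts.sum() else np.empty(0, dtype=np.intp)
        if ia.size == 0:
            continue
        dist = pos[ib] - pos[ia]
        bins = np.minimum((dist - 1) // bin_bp, n_bins - 1).astype(np.intp)
        for lo in range(0, ia.size, block_pairs):
            sl = slice(lo, min(lo + block_pairs, ia.size))
            tables = _pair_counts_block(D, idx[ia[sl]], idx[ib[sl]])
            f = em_haplotype_freqs(tables)
            r2 = r2_from_freqs(f)
            good = ~np.isnan(r2)
            np.add.at(sum_r2, bins[sl][good], r2[good])
            np.add.at(n_pairs, bins[sl][good], 1)

    if n_pairs.sum() == 0:
        log.warning("no qualifying locus pairs for population %s", pop)
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(n_pairs > 0, sum_r2 / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_bp,
        "bin_end": np.arange(1, n_bins + 1) * bin_bp,
        "mean_r2": mean_r2,
        "n_pairs": n_pairs,
    })


def mean_r2_in_range(curve: pd.DataFrame, lo_bp: int, hi_bp: int) -> float:
    """Pair-count-weighted mean r^2 over bins within [lo_bp, hi_bp)."""
    sel = (curve["bin_start"] >= lo_bp) & (curve["bin_end"] <= hi_bp) & (curve["n_pairs"] > 0)
    sub = curve.loc[sel]
    if sub["n_pairs"].sum() == 0:
        return float("nan")
    return float((sub["mean_r2"] * sub["n_pairs"]).sum() / sub["n_pairs"].sum())
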