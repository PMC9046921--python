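"""Weir & Cockerham (1984) variance-component estimator of F_ST.

For each biallelic locus and r populations, with n_i genotyped diploids,
ALT-allele frequency p_i and heterozygote proportion h_i in population i:

    n_bar = sum(n_i) / r
    n_c   = (r * n_bar - sum(n_i^2) / (r * n_bar)) / (r - 1)
    p_bar = sum(n_i * p_i) / (r * n_bar)
    s2    = sum(n_i * (p_i - p_bar)^2) / ((r - 1) * n_bar)
    h_bar = sum(n_i * h_i) / (r * n_bar)

    a = (n_bar / n_c) * (s2 - (p_bar*(1-p_bar) - (r-1)/r * s2 - h_bar/4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar*(1-p_bar) - (r-1)/r * s2 - (2*n_bar - 1)/(4*n_bar) * h_bar)
    c = h_bar / 2

The per-locus estimate is a/(a+b+c); multi-locus (windowed) combination is
the ratio of sums sum(a)/sum(a+b+c), which is stable for windows with few
SNPs.  ``a`` may be negative (the estimator is unbiased around zero when
there is no differentiation); a fixed difference between two populations
gives exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class LocusComponents:
    """Variance components and intermediates at a single locus."""

    a: float
    b: float
    c: float
    n: np.ndarray          # genotyped diploids per population
    p: np.ndarray          # ALT allele frequency per population
    h: np.ndarray          # heterozygote proportion per population
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    r: int

    @property
    def fst(self) -> float:
        den = self.a + self.b + self.c
        return self.a / den if den != 0 else np.nan


def pop_locus_summaries(gm: GenotypeMatrix, pops: list[str]):
    """Per-population (n_i, p_i, h_i) arrays of shape (r, n_variants)."""
    r = len(pops)
    n = np.zeros((r, gm.n_variants))
    p = np.zeros((r, gm.n_variants))
    h = np.zeros((r, gm.n_variants))
    for k, pop in enumerate(pops):
        rows = gm.pop_sample_indices(pop)
        d = gm.dosages[rows]
        called = d != MISSING
        nk = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, d, 0).sum(axis=0) / np.maximum(2 * nk, 1)
            h[k] = (d == 1).sum(axis=0) / np.maximum(nk, 1)
        n[k] = nk
    return n, p, h


def variance_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Vectorised a, b, c over loci from per-population summaries.

    Parameters are arrays of shape (r, L).  Returns ``(a, b, c, usable)``
    where ``usable`` marks loci with every population genotyped and
    ``n_bar > 1`` (others are NaN-safe zeroed and must be excluded from
    window sums by the caller).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")

    n_bar = n.sum(axis=0) / r
    usable = (n > 0).all(axis=0) & (n_bar > 1)
    n_bar_safe = np.where(usable, n_bar, 2.0)

    n_c = (r * n_bar_safe - (n**2).sum(axis=0) / (r * n_bar_safe)) / (r - 1)
    # equal sample sizes make n_c == n_bar but floating subtraction can leave
    # a tiny residue; guard only against exact zero (all samples in one pop)
    n_c = np.where(n_c == 0, np.nan, n_c)

    p_bar = (n * p).sum(axis=0) / (r * n_bar_safe)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar_safe)
    h_bar = (n * h).sum(axis=0) / (r * n_bar_safe)

    pq = p_bar * (1 - p_bar)
    a = (n_bar_safe / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar_safe - 1)
    )
    b = (n_bar_safe / (n_bar_safe - 1)) * (
        pq - (r - 1) / r * s2 - (2 * n_bar_safe - 1) / (4 * n_bar_safe) * h_bar
    )
    c = h_bar / 2

    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c, usable


def locus_components(
    gm: GenotypeMatrix, variant_index: int, pop_a: str, pop_b: str
) -> LocusComponents:
    """Full component breakdown at one locus for a two-population contrast.

    Raises ``ValueError`` if either population has no genotyped sample at
    the locus or the mean sample size is <= 1.
    """
    n, p, h = pop_locus_summaries(gm, [pop_a, pop_b])
    n = n[:, [variant_index]]
    p = p[:, [variant_index]]
    h = h[:, [variant_index]]
    a, b, c, usable = variance_components(n, p, h)
    if not usable[0]:
        raise ValueError(
            f"locus {variant_index} unusable: population sizes {n[:, 0].tolist()}"
        )
    r = 2
    n_bar = float(n.sum() / r)
    n_c = float((r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1))
    p_bar = float((n * p).sum() / (r * n_bar))
    s2 = float((n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    h_bar = float((n * h).sum() / (r * n_bar))
    return LocusComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]),
        n=n[:, 0], p=p[:, 0], h=h[:, 0],
        n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar, r=r,
    )


def fst_ratio_of_sums(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Multi-locus F_ST: sum(a) / sum(a + b + c); NaN if the denominator is 0."""
    den = float((a + b + c).sum())
    return float(a.sum()) / den if den != 0 else float("nan")
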