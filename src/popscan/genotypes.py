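"""In-memory genotype model shared by every analysis stage.

The central container is :class:`GenotypeMatrix`: an (n_samples x n_variants)
diploid dosage matrix (counts of the ALT allele, ``-1`` for missing) together
with per-variant metadata (scaffold, 1-based position, alleles, QUAL), an
optional per-sample depth matrix, and a sample -> population mapping.

Coordinate conventions
----------------------
Variant positions are stored 1-based (VCF convention).  All *intervals*
(windows, sweeps, ROH segments, gene models) are 0-based half-open
internally; a variant at 1-based position ``pos`` falls in the half-open
interval ``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table carries, in order
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with variant metadata and population labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    pops
        Mapping ``sample id -> population label`` covering every sample.
    variants
        DataFrame with columns ``chrom, pos, ref, alt, qual`` sorted by
        (chrom, pos); ``pos`` is 1-based.
    dosages
        ``int8`` array of shape (n_samples, n_variants) with values in
        {0, 1, 2} or ``-1`` (missing).  Dosage counts ALT alleles, so 1 is
        always a heterozygous call.
    depths
        Optional per-sample read depth, same shape as ``dosages``.
    haplotypes
        Optional phased haplotypes of shape (2, n_samples, n_variants);
        populated by the simulator, absent for data read from unphased VCF.
    scaffold_lengths
        Optional scaffold name -> length (bp); used for windowing and VCF
        contig headers.  When absent, the maximum observed position is used.
    """

    samples: list[str]
    pops: dict[str, str]
    variants: pd.DataFrame
    dosages: np.ndarray
    depths: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing_pops = [s for s in self.samples if s not in self.pops]
        if missing_pops:
            raise ValueError(f"samples without population label: {missing_pops}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        v = self.variants
        if len(v) < 2:
            return
        same = v["chrom"].to_numpy()[1:] == v["chrom"].to_numpy()[:-1]
        pos = v["pos"].to_numpy()
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("variants are not sorted by (chrom, pos) or contain duplicates")

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def pop_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.pops[s], None)
        return list(seen)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def pop_sample_indices(self, pop: str) -> np.ndarray:
        """Row indices of the samples belonging to population ``pop``."""
        idx = np.array([i for i, s in enumerate(self.samples) if self.pops[s] == pop], dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"unknown or empty population {pop!r}")
        return idx

    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def scaffold_length(self, chrom: str) -> int:
        """Declared scaffold length, falling back to the last variant position."""
        if chrom in self.scaffold_lengths:
            return self.scaffold_lengths[chrom]
        sel = self.variants["chrom"] == chrom
        if not sel.any():
            raise KeyError(f"no variants and no declared length for scaffold {chrom!r}")
        return int(self.variants.loc[sel, "pos"].max())

    def scaffold_variant_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())

    # -- derived matrices --------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the variant columns in ``index`` (kept order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            depths=None if self.depths is None else self.depths[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            samples=list(self.samples),
            pops=dict(self.pops),
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            depths=None if self.depths is None else self.depths.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    # -- per-population summaries -----------------------------------------
    def allele_counts(self, pop: str, variant_index: np.ndarray | None = None):
        """Non-missing allele count ``n`` and ALT allele count per variant.

        Returns ``(n, alt)`` where ``n`` counts alleles (2 per genotyped
        diploid) and ``alt`` counts ALT alleles among them.
        """
        rows = self.pop_sample_indices(pop)
        d = self.dosages[rows]
        if variant_index is not None:
            d = d[:, variant_index]
        called = d != MISSING
        n = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        return n.astype(np.int64), alt.astype(np.int64)
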