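"""SNP quality-control filters applied between VCF input and the scans.

Three filters mirror a standard short-read resequencing QC recipe:

* ``filter_quality`` — drop sites with Phred QUAL below a cutoff (default
  Q20, i.e. an estimated genotyping error rate above 1%).
* ``filter_spacing`` — require consecutive retained SNPs to be at least
  ``min_spacing`` bp apart (default 5 bp), via a greedy left-to-right scan
  per scaffold that always keeps the first variant.
* ``filter_depth`` — keep sites whose mean depth across samples lies within
  a multiplicative window around the genome-wide mean depth; the window is
  configurable because "k-fold the average depth" recipes vary between
  studies (presets for k = 1, 3, 5 are provided).

All filters are idempotent and commute with partitioning the matrix by
scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

#: (low, high) multiplier presets for the depth window, keyed by fold k:
#: a site passes iff mean site depth is within [mean/k, mean*k].
DEPTH_PRESETS: dict[int, tuple[float, float]] = {1: (1.0, 1.0), 3: (1 / 3, 3.0), 5: (1 / 5, 5.0)}


@dataclass
class FilterConfig:
    min_qual: float = 20.0
    min_spacing: int = 5
    depth_factor_low: float = 1 / 3
    depth_factor_high: float = 3.0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if not (0 < self.depth_factor_low < self.depth_factor_high):
            raise ValueError("require 0 < depth_factor_low < depth_factor_high")


def filter_quality(gm: GenotypeMatrix, min_qual: float = 20.0) -> GenotypeMatrix:
    """Retain variants with QUAL >= ``min_qual`` (boundary inclusive: Q20 keeps 20.0)."""
    qual = gm.variants["qual"].to_numpy()
    keep = np.where(np.isnan(qual), False, qual >= min_qual)
    if min_qual <= 0:
        keep = np.ones(gm.n_variants, dtype=bool)
    return gm.take_variants(keep)


def filter_spacing(gm: GenotypeMatrix, min_spacing: int = 5) -> GenotypeMatrix:
    """Greedy per-scaffold spacing filter.

    Scanning left to right, a variant closer than ``min_spacing`` bp to the
    most recently *retained* variant is dropped; the first variant of each
    scaffold is always retained.
    """
    if min_spacing <= 1:
        return gm.take_variants(np.ones(gm.n_variants, dtype=bool))
    keep = np.zeros(gm.n_variants, dtype=bool)
    pos = gm.variants["pos"].to_numpy()
    for chrom in gm.scaffolds():
        idx = gm.scaffold_variant_indices(chrom)
        last = None
        for j in idx:
            if last is None or pos[j] - last >= min_spacing:
                keep[j] = True
                last = pos[j]
    return gm.take_variants(keep)


def filter_depth(
    gm: GenotypeMatrix,
    low_factor: float = 1 / 3,
    high_factor: float = 3.0,
    genome_mean: float | None = None,
) -> GenotypeMatrix:
    """Keep sites whose mean depth is within [low*mean, high*mean].

    Site depth is the mean per-sample DP at the site; the reference mean is
    the genome-wide mean of site depths unless ``genome_mean`` pins it
    (e.g. to make per-scaffold filtering consistent with a whole-genome
    run).  If the matrix carries no depth information the filter is skipped
    with a warning.
    """
    if gm.depths is None:
        log.warning("no per-sample depths present; depth filter skipped")
        return gm.take_variants(np.ones(gm.n_variants, dtype=bool))
    site_depth = gm.depths.mean(axis=0)
    if site_depth.size == 0:
        return gm.take_variants(np.zeros(0, dtype=bool))
    if genome_mean is None:
        genome_mean = float(site_depth.mean())
    keep = (site_depth >= low_factor * genome_mean) & (site_depth <= high_factor * genome_mean)
    return gm.take_variants(keep)


def apply_filters(gm: GenotypeMatrix, config: FilterConfig | None = None):
    """Run quality -> spacing -> depth and return (filtered matrix, stage report).

    The report is a list of ``(stage, variants_in, variants_out)`` tuples
    suitable for a TSV audit trail.
    """
    config = config or FilterConfig()
    report: list[tuple[str, int, int]] = []

    stages = [
        ("quality", lambda g: filter_quality(g, config.min_qual)),
        ("spacing", lambda g: filter_spacing(g, config.min_spacing)),
        ("depth", lambda g: filter_depth(g, config.depth_factor_low, config.depth_factor_high)),
    ]
    for name, fn in stages:
        n_in = gm.n_variants
        gm = fn(gm)
        report.append((name, n_in, gm.n_variants))
    return gm, report
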