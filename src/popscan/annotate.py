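"""Intersect candidate regions with gene models and compare gene sets
between contrasts (the per-contrast gene lists and Venn/upset counts).

Gene models are consumed from BED (trusted as 0-based half-open) or GFF3
(``gene``-type features only, converted from 1-based inclusive).  A gene is
assigned to a contrast when it overlaps a candidate region by at least one
bp (a minimum-overlap fraction of the gene is available for sensitivity
analysis).  ``overlap_sets`` computes, for every non-empty combination of
contrasts, the number of genes in *exactly* that combination, plus the
intersection across all contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .sweep import CandidateRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    start: int   # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")


def read_bed(path: str | Path) -> list[GeneModel]:
    """BED4+ gene models (chrom, start, end, name[, score, strand])."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"{path}:{line_no}: BED4+ required (chrom start end name)")
        strand = f[5] if len(f) > 5 else "."
        if f[3] in seen:
            continue
        seen.add(f[3])
        genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), strand))
    return genes


def read_gff3(path: str | Path) -> list[GeneModel]:
    """``gene``-type features from GFF3; mRNA/exon children are ignored."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            continue
        seen.add(gid)
        genes.append(GeneModel(gid, feat.seqid, feat.start - 1, feat.end, feat.strand or "."))
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed(path)


@dataclass
class ContrastGeneSet:
    label: str
    genes: frozenset[str]


def regions_to_genes(
    regions: list[CandidateRegion],
    genes: list[GeneModel],
    label: str = "contrast",
    min_overlap_frac: float = 0.0,
) -> ContrastGeneSet:
    """Genes overlapping any candidate region by >= 1 bp (half-open coordinates).

    ``min_overlap_frac`` optionally requires the overlap to cover at least
    that fraction of the gene.  Raises if no region scaffold matches any
    gene scaffold (likely a chromosome-naming mismatch).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.scaffold, IntervalTree()).addi(g.start, g.end, g)

    if regions and trees and not any(r.scaffold in trees for r in regions):
        raise ValueError(
            "no candidate-region scaffold matches any gene scaffold; "
            f"region scaffolds {sorted({r.scaffold for r in regions})[:5]} vs "
            f"gene scaffolds {sorted(trees)[:5]} — check chromosome naming"
        )

    hit: set[str] = set()
    for r in regions:
        tree = trees.get(r.scaffold)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            g: GeneModel = iv.data
            ov = min(r.end, g.end) - max(r.start, g.start)
            if ov > 0 and ov >= min_overlap_frac * (g.end - g.start):
                hit.add(g.gene_id)
    return ContrastGeneSet(label=label, genes=frozenset(hit))


def overlap_sets(sets: list[ContrastGeneSet]):
    """Exact-combination (Venn) counts over >= 2 contrast gene sets.

    Returns ``(membership, counts, full_intersection)`` where ``membership``
    is a genes x contrasts boolean DataFrame, ``counts`` maps each non-empty
    label combination (tuple, sorted by input order) to the number of genes
    in exactly that combination, and ``full_intersection`` is the set of
    genes present in every contrast.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 contrast gene sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("contrast labels must be unique")
    universe = sorted(set().union(*(s.genes for s in sets)))
    membership = pd.DataFrame(
        {s.label: [g in s.genes for g in universe] for s in sets}, index=universe
    )
    counts: dict[tuple[str, ...], int] = {}
    for rsize in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, rsize):
            in_combo = membership[list(combo)].all(axis=1)
            out_combo = ~membership[[l for l in labels if l not in combo]].any(axis=1) \
                if len(combo) < len(labels) else pd.Series(True, index=membership.index)
            counts[combo] = int((in_combo & out_combo).sum())
    full = frozenset.intersection(*(s.genes for s in sets))
    return membership, counts, full
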