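"""VCF and popmap input/output.

Reading goes through :mod:`cyvcf2`; writing emits plain-text VCF 4.2 so that
simulator output, filtered output and round-trip tests all share one code
path.  The popmap is a two-column ``sample<TAB>population`` text file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def read_popmap(path: str | Path) -> dict[str, str]:
    pops: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 'sample<TAB>population', got {line!r}")
        pops[parts[0]] = parts[1]
    return pops


def write_popmap(pops: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\t{p}\n" for s, p in pops.items()))


def read_vcf(
    path: str | Path,
    popmap_path: str | Path | None = None,
    popmap: dict[str, str] | None = None,
    drop_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped by default (``drop_multiallelic=False``
    raises instead — splitting is upstream work for ``bcftools norm``).
    Half-calls and any genotype containing ``.`` are treated as fully
    missing.  Every VCF sample must appear in the popmap.
    """
    if (popmap_path is None) == (popmap is None):
        raise ValueError("provide exactly one of popmap_path or popmap")
    if popmap is None:
        popmap = read_popmap(popmap_path)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(f"VCF samples missing from popmap: {absent}")

    lengths: dict[str, int] = {}
    for name, ln in zip(vcf.seqnames, vcf.seqlens or []):
        lengths[name] = ln

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False

    last = (None, -1)
    for rec in vcf:
        if len(rec.ALT) != 1:
            if drop_multiallelic:
                continue
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        if rec.CHROM == last[0] and rec.POS <= last[1]:
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        last = (rec.CHROM, rec.POS)

        gts = rec.genotypes  # [[a, b, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        dosage_cols.append(col)

        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            depth_cols.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))

        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        qual.append(rec.QUAL if rec.QUAL is not None else np.nan)
    vcf.close()

    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(pos, dtype=np.int64), "ref": ref, "alt": alt,
         "qual": np.array(qual, dtype=float)}
    )
    n_var = len(variants)
    dosages = (
        np.stack(dosage_cols, axis=1) if n_var else np.empty((len(samples), 0), dtype=np.int8)
    )
    depths = None
    if any_depth and n_var:
        depths = np.stack(depth_cols, axis=1)

    return GenotypeMatrix(
        samples=samples,
        pops={s: popmap[s] for s in samples},
        variants=variants,
        dosages=dosages,
        depths=depths,
        scaffold_lengths=lengths,
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as plain VCF 4.2 with GT (and DP if present)."""
    path = Path(path)
    fmt = "GT:DP" if gm.depths is not None else "GT"
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan\n")
        lengths = dict(gm.scaffold_lengths)
        for chrom in gm.scaffolds():
            lengths.setdefault(chrom, gm.scaffold_length(chrom))
        for chrom, ln in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")

        chroms = gm.variants["chrom"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        ref = gm.variants["ref"].to_numpy()
        alt = gm.variants["alt"].to_numpy()
        qual = gm.variants["qual"].to_numpy()
        for j in range(gm.n_variants):
            q = "." if np.isnan(qual[j]) else f"{qual[j]:.6g}"
            fields = [chroms[j], str(pos[j]), ".", ref[j], alt[j], q, "PASS", ".", fmt]
            if gm.depths is not None:
                fields += [
                    f"{_DOSAGE_GT[int(gm.dosages[i, j])]}:{int(gm.depths[i, j])}"
                    for i in range(gm.n_samples)
                ]
            else:
                fields += [_DOSAGE_GT[int(gm.dosages[i, j])] for i in range(gm.n_samples)]
            fh.write("\t".join(fields) + "\n")
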