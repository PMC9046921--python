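"""Runs of homozygosity (ROH) and the genomic inbreeding coefficient F_ROH.

The detector reimplements the classic scanning-window algorithm popularised
by PLINK's ``--homozyg``: slide a window of ``window_snps`` consecutive SNPs
along each scaffold for one sample; a window *passes* if it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls;
each SNP's hit-rate is the fraction of windows containing it that pass, and
the SNP is flagged as being in a homozygous state when the hit-rate reaches
``hit_threshold``.  Maximal runs of flagged SNPs (split at inter-SNP gaps
larger than ``max_gap_kb``) are trimmed to their outermost homozygous
non-missing calls and kept if they satisfy the final length, SNP-count and
density thresholds.

Defaults follow a common resequencing parameterisation: segments of at
least 100 SNPs and 500 kb, at most 50 kb per SNP, gaps below 1000 kb, with
50-SNP windows allowing 2 heterozygous and 5 missing calls.  The behaviour
is PLINK-*like*: PLINK's exact internal het allowance inside final segments
is not documented, so segments here are trimmed to outermost homozygous
calls and interior heterozygotes survive only via the hit-rate mechanism.

F_ROH for a sample is the summed ROH length divided by the total autosome
length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class ROHParams:
    min_snps: int = 100
    min_kb: float = 500.0
    density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    window_snps: int = 50
    window_max_het: int = 2
    window_max_missing: int = 5
    hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        vals = (self.min_snps, self.min_kb, self.density_kb_per_snp,
                self.max_gap_kb, self.window_snps, self.hit_threshold)
        if any(v <= 0 for v in vals):
            raise ValueError("all ROH parameters must be positive")
        if self.window_snps > self.min_snps:
            raise ValueError("window_snps must not exceed min_snps")


@dataclass
class ROHSegment:
    """One homozygous run; coordinates 0-based half-open over SNP positions."""

    sample: str
    scaffold: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def _flag_homozygous_state(dos: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP homozygous-state flags from the scanning-window hit-rate."""
    L = dos.size
    w = params.window_snps
    if L < w:
        return np.zeros(L, dtype=bool)
    het = (dos == 1).astype(np.int32)
    mis = (dos == MISSING).astype(np.int32)
    # sliding sums over windows [i, i+w)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    win_het = ch[w:] - ch[:-w]
    win_mis = cm[w:] - cm[:-w]
    passing = ((win_het <= params.window_max_het) & (win_mis <= params.window_max_missing))
    n_win = L - w + 1
    # windows containing SNP i: start indices in [max(0, i-w+1), min(i, n_win-1)]
    cp = np.concatenate([[0], np.cumsum(passing.astype(np.int64))])
    i = np.arange(L)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    hits = cp[hi + 1] - cp[lo]
    total = hi - lo + 1
    return hits / total >= params.hit_threshold


def scan_sample(gm: GenotypeMatrix, sample: str, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments for one sample across all scaffolds."""
    params = params or ROHParams()
    si = gm.sample_index(sample)
    pos_all = gm.variants["pos"].to_numpy()
    segments: list[ROHSegment] = []
    max_gap_bp = params.max_gap_kb * 1000.0

    for chrom in gm.scaffolds():
        idx = gm.scaffold_variant_indices(chrom)
        dos = gm.dosages[si, idx]
        pos = pos_all[idx]
        if dos.size < params.window_snps:
            log.warning("scaffold %s has %d SNPs < window of %d; no ROH calls",
                        chrom, dos.size, params.window_snps)
            continue
        flags = _flag_homozygous_state(dos, params)

        # break flagged runs at large physical gaps
        gap_break = np.zeros(dos.size, dtype=bool)
        gap_break[1:] = np.diff(pos) > max_gap_bp
        run_start = None
        boundaries: list[tuple[int, int]] = []
        for j in range(dos.size):
            if flags[j]:
                if run_start is None:
                    run_start = j
                elif gap_break[j]:  # gap between j-1 and j exceeds max_gap
                    boundaries.append((run_start, j))
                    run_start = j
            elif run_start is not None:
                boundaries.append((run_start, j))
                run_start = None
        if run_start is not None:
            boundaries.append((run_start, dos.size))

        for lo, hi in boundaries:
            seg = _finalize_run(sample, chrom, dos, pos, lo, hi, params)
            if seg is not None:
                segments.append(seg)
    return segments


def _finalize_run(sample, chrom, dos, pos, lo, hi, params: ROHParams) -> ROHSegment | None:
    """Trim a flagged run to outermost homozygous calls and apply final filters."""
    hom = (dos[lo:hi] == 0) | (dos[lo:hi] == 2)
    if not hom.any():
        return None
    first = lo + int(np.argmax(hom))
    last = lo + len(hom) - 1 - int(np.argmax(hom[::-1]))
    n_snps = last - first + 1
    start0 = int(pos[first]) - 1
    end0 = int(pos[last])
    length_kb = (end0 - start0) / 1000.0
    if n_snps < params.min_snps:
        return None
    if length_kb < params.min_kb:
        return None
    if length_kb / n_snps > params.density_kb_per_snp:
        return None
    return ROHSegment(sample=sample, scaffold=chrom, start=start0, end=end0, n_snps=n_snps)


def scan_all(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    params = params or ROHParams()
    out: list[ROHSegment] = []
    for s in gm.samples:
        out.extend(scan_sample(gm, s, params))
    return out


@dataclass
class InbreedingReport:
    sample: str
    l_roh: int    # summed ROH length, bp
    l_auto: int   # total autosome length, bp

    @property
    def f_roh(self) -> float:
        return self.l_roh / self.l_auto


def f_roh(
    segments: list[ROHSegment],
    autosome_lengths: dict[str, int],
    samples: list[str] | None = None,
) -> list[InbreedingReport]:
    """Per-sample F_ROH = total ROH bp / total autosome bp.

    ``autosome_lengths`` must cover every scaffold a segment lies on (sex
    scaffolds should simply be omitted upstream).  ``samples`` fixes the
    report order and includes samples with no segments (F_ROH = 0).
    """
    l_auto = int(sum(autosome_lengths.values()))
    if l_auto <= 0:
        raise ValueError("autosome table is empty")
    per_sample: dict[str, int] = {}
    for seg in segments:
        if seg.scaffold not in autosome_lengths:
            raise ValueError(
                f"segment on scaffold {seg.scaffold!r} absent from autosome table"
            )
        per_sample[seg.sample] = per_sample.get(seg.sample, 0) + seg.length_bp
    order = samples if samples is not None else sorted(per_sample)
    return [InbreedingReport(s, per_sample.get(s, 0), l_auto) for s in order]


def breed_summary(
    reports: list[InbreedingReport],
    segments: list[ROHSegment],
    pops: dict[str, str],
) -> pd.DataFrame:
    """Per-population means: segment count, total ROH length, F_ROH."""
    seg_count: dict[str, int] = {}
    for seg in segments:
        seg_count[seg.sample] = seg_count.get(seg.sample, 0) + 1
    rows = []
    for rep in reports:
        rows.append((pops[rep.sample], rep.sample, seg_count.get(rep.sample, 0),
                     rep.l_roh, rep.f_roh))
    df = pd.DataFrame(rows, columns=["pop", "sample", "n_segments", "l_roh", "f_roh"])
    return (
        df.groupby("pop", sort=False)
        .agg(n_samples=("sample", "size"), mean_n_segments=("n_segments", "mean"),
             mean_l_roh=("l_roh", "mean"), mean_f_roh=("f_roh", "mean"))
        .reset_index()
    )


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """PLINK .hom-style table (positions converted to 1-based inclusive)."""
    rows = [(s.sample, s.scaffold, s.start + 1, s.end, s.n_snps, s.length_kb)
            for s in segments]
    return pd.DataFrame(rows, columns=["sample", "scaffold", "pos1", "pos2", "n_snps", "kb"])
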