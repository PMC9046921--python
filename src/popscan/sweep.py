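"""Sliding-window selective-sweep scan.

The scan contrasts a *target* population against a *control* population in
overlapping windows (40 kb with 20 kb increments by default):

* windowed F_ST — Weir & Cockerham components summed over the loci of each
  window (ratio of sums);
* windowed nucleotide diversity theta_pi per population — per-site unbiased
  heterozygosity ``2 * c_ref * c_alt / (n * (n - 1))`` summed over window
  sites and divided by the window span in bp;
* ``log2(pi_control / pi_target)`` — large positive values mean diversity
  lost in the target, the classic footprint of a recent sweep;
* joint outliers — windows in the top ``q`` (default 5%) empirical tail of
  *both* statistics simultaneously, merged into candidate regions.

Windows are anchored at coordinate 0 of each scaffold and stored 0-based
half-open; the final window of a scaffold may be truncated.  Windows with
fewer than ``min_snps`` usable loci (default 10) are excluded from the
quantile computation and can never be outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import pop_locus_summaries, variance_components
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 40_000
DEFAULT_STEP = 20_000
DEFAULT_MIN_SNPS = 10


@dataclass
class CandidateRegion:
    """Maximal run of overlapping / book-ended outlier windows on one scaffold."""

    scaffold: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_log2_ratio: float
    window_rows: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(scaffold_length: int, size: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP):
    """(start, end) pairs, 0-based half-open, anchored at 0; last window truncated."""
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    starts = np.arange(0, max(scaffold_length, 1), step, dtype=np.int64)
    ends = np.minimum(starts + size, scaffold_length)
    keep = ends > starts
    return starts[keep], ends[keep]


def _window_locus_slices(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """Index ranges (lo, hi) of sorted 0-based locus positions per window."""
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi


def site_pi(n: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity 2*c_ref*c_alt / (n*(n-1)).

    ``n`` is the non-missing allele count; sites with n < 2 contribute 0.
    """
    n = np.asarray(n, dtype=float)
    alt = np.asarray(alt, dtype=float)
    ok = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * (n - alt) * alt / (n * (n - 1.0))
    return np.where(ok, pi, 0.0)


def scan_windows(
    gm: GenotypeMatrix,
    target_pop: str,
    control_pop: str,
    size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Per-window statistics table for one (target, control) contrast.

    Columns: scaffold, start, end, n_snps, fst_num, fst_den, fst, pi_target,
    pi_control, log2_ratio, usable.  ``log2_ratio`` is ``+inf`` when the
    target has zero diversity in a window where the control does not; a
    window where both diversities are zero, or with fewer than ``min_snps``
    loci, or with zero F_ST denominator, is flagged unusable.
    """
    n, p, h = pop_locus_summaries(gm, [target_pop, control_pop])
    a, b, c, locus_ok = variance_components(n, p, h)
    d = a + b + c

    nt, altt = gm.allele_counts(target_pop)
    nc_, altc = gm.allele_counts(control_pop)
    pi_t = site_pi(nt, altt)
    pi_c = site_pi(nc_, altc)

    pos0 = gm.variants["pos"].to_numpy() - 1
    chrom_arr = gm.variants["chrom"].to_numpy()

    rows = []
    for chrom in gm.scaffolds():
        idx = np.flatnonzero(chrom_arr == chrom)
        cpos = pos0[idx]
        starts, ends = make_windows(gm.scaffold_length(chrom), size, step)
        lo, hi = _window_locus_slices(cpos, starts, ends)

        ca = np.concatenate([[0.0], np.cumsum(a[idx] * locus_ok[idx])])
        cd = np.concatenate([[0.0], np.cumsum(d[idx] * locus_ok[idx])])
        cn = np.concatenate([[0], np.cumsum(locus_ok[idx].astype(np.int64))])
        cpt = np.concatenate([[0.0], np.cumsum(pi_t[idx])])
        cpc = np.concatenate([[0.0], np.cumsum(pi_c[idx])])

        span = (ends - starts).astype(float)
        w_num = ca[hi] - ca[lo]
        w_den = cd[hi] - cd[lo]
        w_n = cn[hi] - cn[lo]
        w_pit = (cpt[hi] - cpt[lo]) / span
        w_pic = (cpc[hi] - cpc[lo]) / span

        for k in range(len(starts)):
            rows.append((chrom, int(starts[k]), int(ends[k]), int(w_n[k]),
                         w_num[k], w_den[k], w_pit[k], w_pic[k]))

    df = pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "n_snps", "fst_num", "fst_den",
                 "pi_target", "pi_control"],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        df["fst"] = df["fst_num"] / df["fst_den"]
        ratio = df["pi_control"] / df["pi_target"]
        df["log2_ratio"] = np.log2(ratio)
    # pi_target == 0, pi_control > 0: strongest possible signal, +inf sentinel
    df.loc[(df["pi_target"] == 0) & (df["pi_control"] > 0), "log2_ratio"] = np.inf
    # both diversities zero: the ratio carries no information -> NaN, the
    # window still enters the F_ST quantile but can never be a joint outlier
    df.loc[(df["pi_target"] == 0) & (df["pi_control"] == 0), "log2_ratio"] = np.nan
    df["usable"] = (df["n_snps"] >= min_snps) & (df["fst_den"] > 0)
    return df


def nearest_rank_top_threshold(values: np.ndarray, q: float) -> float:
    """Value of the k-th largest element with k = ceil(q * n) (nearest rank).

    Everything >= this threshold belongs to the top-q tail, ties included.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no values")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = int(np.ceil(q * n))
    k = min(max(k, 1), n)
    return float(np.sort(values)[n - k])


def joint_outliers(stats: pd.DataFrame, q: float = 0.05, min_usable: int = 20):
    """Flag windows in the top-q tails of both F_ST and log2 pi-ratio.

    Thresholds are empirical nearest-rank quantiles over *usable* windows
    only; ties at the threshold are included.  Returns ``(outlier_mask,
    fst_threshold, ratio_threshold)``.  Raises if fewer than ``min_usable``
    usable windows exist.
    """
    usable = stats["usable"].to_numpy()
    n_usable = int(usable.sum())
    if n_usable < min_usable:
        raise ValueError(f"only {n_usable} usable windows (< {min_usable}); scan not meaningful")
    fst = stats["fst"].to_numpy(dtype=float)
    ratio = stats["log2_ratio"].to_numpy(dtype=float)
    fst_thr = nearest_rank_top_threshold(fst[usable], q)
    ratio_ok = usable & ~np.isnan(ratio)
    if not ratio_ok.any():
        raise ValueError("no window has a defined log2 pi-ratio")
    ratio_thr = nearest_rank_top_threshold(ratio[ratio_ok], q)
    with np.errstate(invalid="ignore"):
        mask = usable & (fst >= fst_thr) & ratio_ok & (ratio >= ratio_thr)
    return mask, fst_thr, ratio_thr


def merge_regions(stats: pd.DataFrame, outlier_mask: np.ndarray) -> list[CandidateRegion]:
    """Merge overlapping or book-ended outlier windows into candidate regions."""
    sub = stats.loc[np.asarray(outlier_mask)].sort_values(["scaffold", "start"])
    regions: list[CandidateRegion] = []
    cur: CandidateRegion | None = None
    for row_idx, row in sub.iterrows():
        if cur is not None and row["scaffold"] == cur.scaffold and row["start"] <= cur.end:
            cur.end = max(cur.end, int(row["end"]))
            cur.n_windows += 1
            cur.max_fst = max(cur.max_fst, float(row["fst"]))
            cur.max_log2_ratio = max(cur.max_log2_ratio, float(row["log2_ratio"]))
            cur.window_rows.append(int(row_idx))
        else:
            cur = CandidateRegion(
                scaffold=str(row["scaffold"]), start=int(row["start"]), end=int(row["end"]),
                n_windows=1, max_fst=float(row["fst"]),
                max_log2_ratio=float(row["log2_ratio"]), window_rows=[int(row_idx)],
            )
            regions.append(cur)
    return regions


def sweep_scan(
    gm: GenotypeMatrix,
    target_pop: str,
    control_pop: str,
    size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
    q: float = 0.05,
):
    """Full contrast: window stats + outlier flags + merged candidate regions.

    Returns ``(stats, regions, thresholds)`` where ``stats`` gains an
    ``outlier`` column and ``thresholds`` is ``{"fst": ..., "log2_ratio": ...}``.
    """
    stats = scan_windows(gm, target_pop, control_pop, size, step, min_snps)
    mask, fst_thr, ratio_thr = joint_outliers(stats, q)
    stats = stats.copy()
    stats["outlier"] = mask
    regions = merge_regions(stats, mask)
    return stats, regions, {"fst": fst_thr, "log2_ratio": ratio_thr}


def regions_to_bed(regions: list[CandidateRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\tregion_{i}\t{r.max_fst:.6g}\n")
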