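"""Independent brute-force oracles, written as direct transcriptions of the
defining formulas and deliberately sharing no code with the implementation.
"""

from __future__ import annotations

import itertools
import math


def wc_components_oracle(pop_genotypes: list[list[int]]):
    """Weir-Cockerham a, b, c at one locus from per-population genotype lists.

    Each genotype is an ALT-allele dosage in {0, 1, 2}; missing genotypes are
    simply absent from the lists.  Plain-float transcription of the
    variance-component formulas.
    """
    r = len(pop_genotypes)
    n = [len(g) for g in pop_genotypes]
    p = [sum(g) / (2 * len(g)) for g in pop_genotypes]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pop_genotypes]

    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def site_pi_oracle(genotypes: list[int]) -> float:
    """Average pairwise difference per site: 2*c_ref*c_alt / (n*(n-1))."""
    alleles = []
    for g in genotypes:
        alleles += [1] * g + [0] * (2 - g)
    n = len(alleles)
    if n < 2:
        return 0.0
    alt = sum(alleles)
    return 2 * (n - alt) * alt / (n * (n - 1))


def top_q_joint_oracle(scores_a: list[float], scores_b: list[float], q: float):
    """Indices in the top-q tail of both score lists (k-th-largest threshold,
    ties included), by explicit sorting."""
    n = len(scores_a)
    k = max(1, math.ceil(q * n))
    thr_a = sorted(scores_a, reverse=True)[k - 1]
    thr_b = sorted(scores_b, reverse=True)[k - 1]
    return {i for i in range(n) if scores_a[i] >= thr_a and scores_b[i] >= thr_b}


def merge_intervals_oracle(intervals: list[tuple[str, int, int]]):
    """Union-find merge of overlapping/book-ended intervals per scaffold."""
    parent = list(range(len(intervals)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(intervals)), 2):
        ci, si, ei = intervals[i]
        cj, sj, ej = intervals[j]
        if ci == cj and si <= ej and sj <= ei:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)
    out = set()
    for members in groups.values():
        chrom = intervals[members[0]][0]
        out.add((chrom, min(intervals[m][1] for m in members),
                 max(intervals[m][2] for m in members)))
    return out


def venn_counts_oracle(named_sets: dict[str, set]):
    """Exact-combination counts by iterating over the union, per element."""
    labels = list(named_sets)
    counts: dict[tuple[str, ...], int] = {}
    for rsize in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, rsize):
            counts[combo] = 0
    universe = set().union(*named_sets.values())
    for g in universe:
        combo = tuple(l for l in labels if g in named_sets[l])
        counts[combo] += 1
    return counts


def genes_in_regions_oracle(regions, genes):
    """All-pairs >=1 bp half-open overlap test."""
    hit = set()
    for rchrom, rstart, rend in regions:
        for gid, gchrom, gstart, gend in genes:
            if gchrom == rchrom and max(rstart, gstart) < min(rend, gend):
                hit.add(gid)
    return hit


def roh_rescan_oracle(positions, dosages, params):
    """Straightforward re-implementation of the scanning-window ROH calls.

    Quadratic and index-based rather than cumulative-sum based; used to
    cross-check segment calls on small fixtures.
    """
    L = len(positions)
    w = params.window_snps
    if L < w:
        return []
    passing = []
    for s in range(L - w + 1):
        win = dosages[s:s + w]
        passing.append(
            sum(1 for g in win if g == 1) <= params.window_max_het
            and sum(1 for g in win if g == -1) <= params.window_max_missing
        )
    flags = []
    for i in range(L):
        wins = [s for s in range(max(0, i - w + 1), min(i, L - w) + 1)]
        hits = sum(1 for s in wins if passing[s])
        flags.append(hits / len(wins) >= params.hit_threshold)

    segments = []
    run = []
    for i in range(L):
        if flags[i]:
            if run and positions[i] - positions[run[-1]] > params.max_gap_kb * 1000:
                segments.append(run)
                run = []
            run.append(i)
        elif run:
            segments.append(run)
            run = []
    if run:
        segments.append(run)

    out = []
    for run in segments:
        hom = [i for i in run if dosages[i] in (0, 2)]
        if not hom:
            continue
        first, last = hom[0], hom[-1]
        n_snps = last - first + 1
        length_kb = (positions[last] - positions[first] + 1) / 1000
        if n_snps < params.min_snps or length_kb < params.min_kb:
            continue
        if length_kb / n_snps > params.density_kb_per_snp:
            continue
        out.append((positions[first], positions[last], n_snps))
    return out


def pair_r2_direct_oracle(da, db):
    """r^2 by direct haplotype counting; valid only when no individual is
    heterozygous at both loci (phase unambiguous)."""
    haps = []
    for ga, gb in zip(da, db):
        if ga < 0 or gb < 0:
            continue
        assert not (ga == 1 and gb == 1), "ambiguous pair in direct oracle"
        if ga == 1:
            haps += [(0, gb // 2), (1, gb // 2)]
        elif gb == 1:
            haps += [(ga // 2, 0), (ga // 2, 1)]
        else:
            haps += [(ga // 2, gb // 2)] * 2
    n = len(haps)
    pa = sum(h[0] for h in haps) / n
    pb = sum(h[1] for h in haps) / n
    pab = sum(1 for h in haps if h == (1, 1)) / n
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))
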