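"""Population-structure summaries: allele-sharing distance, neighbor-joining
tree with bootstrap support, and genotype PCA.

Distance: the allele-sharing (IBS) distance between diploid samples i, j is

    d(i, j) = mean over shared non-missing loci of |g_i - g_j| / 2

so identical genotypes give 0 and opposite homozygotes give 1.

Tree: Saitou & Nei's neighbor-joining on the distance matrix, with the
lowest-index pair as deterministic tie-break; NJ reproduces additive
distance matrices exactly.  Negative branch lengths are clamped to 0 with
the deficit transferred to the sister branch.  Bootstrap support resamples
loci with replacement, recomputes distance + NJ, and reports for each
internal edge of the full-data tree the percentage of replicates containing
the same leaf bipartition.

PCA: genotypes are normalised per locus as ``(g - 2p) / sqrt(2p(1-p))``
with p the sample ALT frequency (the standard variance-scaled genotype
normalisation of EIGENSOFT); missing entries are imputed to 0 (the column
mean) after centering, monomorphic loci dropped, and the top axes extracted
by SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def allele_sharing_distance(
    gm: GenotypeMatrix, variant_index: np.ndarray | None = None
) -> tuple[list[str], np.ndarray]:
    """(sample ids, symmetric matrix) of pairwise allele-sharing distances.

    Raises ``ValueError`` naming the first sample pair that shares no
    non-missing locus.
    """
    D = gm.dosages if variant_index is None else gm.dosages[:, variant_index]
    D = D.astype(np.float64)
    miss = D == MISSING
    if not miss.any():
        if D.shape[1] == 0:
            raise ValueError("no variants")
        mat = cdist(D, D, metric="cityblock") / (2.0 * D.shape[1])
    else:
        Dm = np.where(miss, 0.0, D)
        ok = (~miss).astype(np.float64)
        shared = ok @ ok.T
        if (shared == 0).any():
            i, j = np.argwhere(shared == 0)[0]
            raise ValueError(
                f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no genotyped locus"
            )
        n = D.shape[0]
        mat = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(Dm - Dm[i]) * ok * ok[i]
            mat[i] = diff.sum(axis=1) / (2.0 * shared[i])
    np.fill_diagonal(mat, 0.0)
    return list(gm.samples), (mat + mat.T) / 2.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted representation of an unrooted tree (root is the final 3-way join)."""

    name: str | None = None
    length: float = 0.0          # branch length to parent
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(ch._newick_node() for ch in self.children)
        label = "" if self.support is None else f"{self.support:.10g}"
        return f"({inner}){label}:{self.length:.10g}"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, one canonical frozenset per internal edge."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset] = set()

        def walk(node: TreeNode):
            below = frozenset(node.leaf_names())
            if node is not self and not node.is_leaf:
                side = below if len(below) <= len(all_leaves - below) else all_leaves - below
                if 2 <= len(side) <= len(all_leaves) - 2:
                    if len(side) * 2 == len(all_leaves):
                        side = min(side, all_leaves - side, key=lambda s: sorted(s))
                    parts.add(side)
            for ch in node.children:
                walk(ch)

        walk(self)
        return parts

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Path-length matrix between all leaves (NJ on additive input inverts this)."""
        leaves = self.leaves()
        names = [lf.name for lf in leaves]
        index = {id(lf): k for k, lf in enumerate(leaves)}
        n = len(leaves)
        mat = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {index[id(node)]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for ch in node.children:
                m = {k: v + ch.length for k, v in walk(ch).items()}
                child_maps.append(m)
            for i_map in range(len(child_maps)):
                for j_map in range(i_map + 1, len(child_maps)):
                    for ki, di in child_maps[i_map].items():
                        for kj, dj in child_maps[j_map].items():
                            mat[ki, kj] = mat[kj, ki] = di + dj
            for m in child_maps:
                below.update(m)
            return below

        walk(self)
        return names, mat


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative limb at 0, moving the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(names: list[str], dm: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: ties in the Q criterion resolve to the lowest index pair.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 samples for a tree")
    if dm.shape != (n, n) or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    D = dm.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: argmin of flattened row-major scan
        flat = np.argmin(Q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = TreeNode(children=[ni, nj_])

        dnew = (D[i] + D[j] - D[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    (x, y, z) = nodes
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    lx = (dxy + dxz - dyz) / 2
    ly = (dxy + dyz - dxz) / 2
    lz = (dxz + dyz - dxy) / 2
    x.length, y.length, z.length = (max(v, 0.0) for v in (lx, ly, lz))
    return TreeNode(children=[x, y, z])


def bootstrap_support(
    gm: GenotypeMatrix, n_reps: int = 1000, seed: int | None = None,
    tree: TreeNode | None = None,
) -> TreeNode:
    """Attach bootstrap support (%) to the internal nodes of the NJ tree.

    Each replicate resamples loci with replacement, recomputes the
    allele-sharing distance and the NJ tree, and counts how often each
    internal bipartition of the full-data tree recurs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names, dm = allele_sharing_distance(gm)
    if tree is None:
        tree = nj_tree(names, dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = gm.n_variants
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        _, bdm = allele_sharing_distance(gm, variant_index=idx)
        reps = nj_tree(names, bdm).bipartitions()
        for bp in target:
            if bp in reps:
                counts[bp] += 1

    def annotate(node: TreeNode):
        if node is not tree and not node.is_leaf:
            all_leaves = frozenset(tree.leaf_names())
            below = frozenset(node.leaf_names())
            side = below if len(below) <= len(all_leaves - below) else all_leaves - below
            if len(side) * 2 == len(all_leaves):
                side = min(side, all_leaves - side, key=lambda s: sorted(s))
            if side in counts:
                node.support = 100.0 * counts[side] / n_reps
        for ch in node.children:
            annotate(ch)

    annotate(tree)
    return tree


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    samples: list[str]
    eigenvalues: np.ndarray       # full spectrum, descending
    coords: np.ndarray            # (n_samples, k) principal-component scores
    loadings: np.ndarray | None = None


def genotype_pca(gm: GenotypeMatrix, k: int = 10, return_loadings: bool = False) -> PCAResult:
    """PCA of variance-normalised genotypes.

    Monomorphic loci are dropped; missing genotypes contribute 0 after
    centering (mean imputation).  Eigenvalues are those of the sample
    covariance of the normalised matrix, descending.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    D = gm.dosages.astype(np.float64)
    miss = D == MISSING
    called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(miss, 0.0, D).sum(axis=0) / (2.0 * np.maximum(called, 1))
    poly = (called > 0) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci")
    Dp = D[:, poly]
    pj = p[poly]
    M = (Dp - 2.0 * pj) / np.sqrt(2.0 * pj * (1.0 - pj))
    M[miss[:, poly]] = 0.0

    kmax = gm.n_samples - 1
    if k > kmax:
        log.warning("k=%d truncated to %d (n_samples - 1)", k, kmax)
        k = kmax
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # sign convention: largest-magnitude coordinate of each axis positive
    for a in range(U.shape[1]):
        col = U[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, a] = -col
            Vt[a] = -Vt[a]
    eigvals = (S**2) / M.shape[1]
    coords = U[:, :k] * S[:k]
    return PCAResult(
        samples=list(gm.samples),
        eigenvalues=eigvals,
        coords=coords,
        loadings=Vt[:k].T if return_loadings else None,
    )


def write_phylip(names: list[str], dm: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for i, nm in enumerate(names):
            row = " ".join(f"{v:.8f}" for v in dm[i])
            fh.write(f"{nm:<10s} {row}\n")
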