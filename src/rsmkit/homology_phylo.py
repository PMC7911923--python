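"""Pairwise homology and UPGMA clustering of Rsm sRNA sequences.

Percent identity between tandem sRNA copies is computed from an optimal
global (Needleman-Wunsch) alignment; pairwise identities feed a distance
matrix (d = 1 - identity) clustered by classic UPGMA into an ultrametric
tree, as used to sort rsmX/rsmY/rsmZ genes into family clades.

Identity uses the full alignment length (gap columns included) as the
denominator.  Trees are exported as Newick via scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

GAP = -2.0
MATCH = 1.0
MISMATCH = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    a_aln: str
    b_aln: str
    score: float
    identity: float


def global_align(
    a: str,
    b: str,
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap: float = GAP,
) -> PairwiseAlignment:
    """Optimal global alignment with linear gap cost.

    Traceback is deterministic: on ties, diagonal is preferred over a gap in
    ``b`` (up) over a gap in ``a`` (left).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    F = np.empty((n + 1, m + 1))
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    jdx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        best = np.maximum(F[i - 1, :-1] + sub, F[i - 1, 1:] + gap)
        # left-gap dependency resolved as a running maximum:
        # F[i,j] = max_{k<=j} (best'[k] - gap_run) with best'[0] = F[i,0]
        cand = np.concatenate(([F[i, 0]], best - gap * jdx))
        F[i, 1:] = np.maximum.accumulate(cand)[1:] + gap * jdx
    # traceback, diagonal > up > left on ties
    i, j = n, m
    a_aln: list[str] = []
    b_aln: list[str] = []
    matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if F[i, j] == F[i - 1, j - 1] + s:
                a_aln.append(a[i - 1])
                b_aln.append(b[j - 1])
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + gap:
            a_aln.append(a[i - 1])
            b_aln.append("-")
            i -= 1
            continue
        a_aln.append("-")
        b_aln.append(b[j - 1])
        j -= 1
    a_s = "".join(reversed(a_aln))
    b_s = "".join(reversed(b_aln))
    return PairwiseAlignment(a_s, b_s, float(F[n, m]), matches / len(a_s))


def percent_identity(aln: PairwiseAlignment) -> float:
    """Matching columns over total alignment columns (gaps in denominator)."""
    if len(aln.a_aln) != len(aln.b_aln) or not aln.a_aln:
        raise ValueError("invalid alignment")
    matches = sum(
        1 for x, y in zip(aln.a_aln, aln.b_aln) if x == y and x != "-"
    )
    return matches / len(aln.a_aln)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0,1]

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    """d[i][j] = 1 - percent_identity of the optimal global alignment."""
    labels = tuple(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[labels[i]], seqs[labels[j]])
            d[i, j] = d[j, i] = 1.0 - percent_identity(aln)
    return DistanceMatrix(labels, d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Classic UPGMA (arithmetic-mean linkage) producing an ultrametric tree.

    At each step the pair of clusters at minimal distance is merged; ties are
    broken by the lexicographically smallest (min-leaf-label) pair.  The new
    node sits at height d/2; branch lengths are height differences.  Node
    heights are kept in ``node.height``.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    nodes: dict[str, TreeNode] = {}
    heights: dict[str, float] = {}
    sizes: dict[str, int] = {}
    dist: dict[frozenset[str], float] = {}
    active = list(dm.labels)
    for lab in dm.labels:
        node = TreeNode(name=lab)
        node.height = 0.0
        nodes[lab], heights[lab], sizes[lab] = node, 0.0, 1
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.d[i, j])

    while len(active) > 1:
        best_key = min(
            (
                (dist[frozenset((p, q))], tuple(sorted((p, q))))
                for i, p in enumerate(active)
                for q in active[i + 1 :]
            ),
        )
        d_min, (p, q) = best_key
        parent = TreeNode()
        h = d_min / 2.0
        parent.height = h
        for child_key in (p, q):
            child = nodes[child_key]
            child.length = h - heights[child_key]
            parent.append(child)
        key = min(p, q)  # cluster named by its smallest leaf label
        other = max(p, q)
        new_size = sizes[p] + sizes[q]
        active.remove(p)
        active.remove(q)
        for r in active:
            d_new = (
                sizes[p] * dist[frozenset((p, r))] + sizes[q] * dist[frozenset((q, r))]
            ) / new_size
            dist[frozenset((key, r))] = d_new
        nodes[key], heights[key], sizes[key] = parent, h, new_size
        nodes.pop(other, None)
        active.append(key)
        active.sort()

    root = nodes[active[0]]
    root.length = None
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol


def clades(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets of all internal nodes (including the root)."""
    out = []
    for node in tree.non_tips(include_self=True):
        out.append(frozenset(t.name for t in node.tips()))
    return out


def is_monophyletic(tree: TreeNode, labels: set[str]) -> bool:
    return frozenset(labels) in clades(tree)
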