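"""N-terminal-domain phylogeny: pairwise distances, neighbor joining,
bootstrap support.

Spidroin family relationships are read from the conserved N-terminal
domains: the first 100 amino acids of each protein are compared by global
pairwise alignment (BLOSUM62, affine gaps) and the resulting p-distances
(1 - identity over aligned non-gap columns) feed canonical Saitou-Nei
neighbor joining.  In place of a progressive multiple alignment, bootstrap
resampling draws columns from a stacked pad-to-longest pseudo-alignment;
supports are the percentage of replicates containing each internal
bipartition of the point-estimate tree.

Trees are scikit-bio ``TreeNode`` objects (newick IO comes for free);
distance matrices are scikit-bio ``DistanceMatrix`` objects.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "n_terminal_region", "align_and_distance", "distance_matrix",
    "neighbor_joining", "bootstrap_support", "tree_bipartitions",
    "path_length_matrix",
]


def n_terminal_region(protein: str, n: int = 100) -> tuple[str, bool]:
    """First min(n, length) residues; the flag marks truncated input
    (sequence shorter than n, or n == 0)."""
    if not protein:
        raise ValueError("empty protein sequence")
    return protein[:n], len(protein) < n or n == 0


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


def align_and_distance(a: str, b: str) -> float:
    """p-distance from a global pairwise alignment: 1 - identical columns /
    aligned non-gap columns (columns with a gap in either sequence are
    excluded from both counts)."""
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    if b < a:  # co-optimal alignments can differ by argument order;
        a, b = b, a  # canonical ordering keeps the distance symmetric
    aln = _aligner().align(a, b)[0]
    sa, sb = aln[0], aln[1]
    same = valid = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        valid += 1
        same += x == y
    if valid == 0:
        return 1.0
    return 1.0 - same / valid


def distance_matrix(sequences: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distance matrix over labelled sequences."""
    labels = [name for name, _ in sequences]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = align_and_distance(sequences[i][1], sequences[j][1])
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Pair selection minimizes the Q criterion with ties broken by the
    lowest label-index pair; negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge; the final three taxa are
    resolved by the closed-form star formulas.
    """
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    d = {(a, b): float(dm[a, b]) for a in labels for b in labels}
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    order = {l: i for i, l in enumerate(labels)}
    active = list(labels)
    if len(active) == 2:
        a, b = active
        half = d[(a, b)] / 2.0
        root = TreeNode()
        nodes[a].length = nodes[b].length = half
        root.extend([nodes[a], nodes[b]])
        return root
    join_idx = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        da = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2.0 * (n - 2))
        db = d[(a, b)] - da
        # clamp negatives, moving the deficit to the sibling edge
        if da < 0:
            db += da
            da = 0.0
        if db < 0:
            da += db
            db = 0.0
        new = f"__join{join_idx}"
        join_idx += 1
        parent = TreeNode()
        nodes[a].length = max(da, 0.0)
        nodes[b].length = max(db, 0.0)
        parent.extend([nodes[a], nodes[b]])
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        d[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]
        order[new] = max(order.values()) + 1
    a, b, c = sorted(active, key=lambda x: order[x])
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    root = TreeNode()
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions (as frozensets of the smaller-side taxon
    names, with deterministic canonical side) of an unrooted tree."""
    taxa = frozenset(t.name for t in tree.tips())
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return bips


def path_length_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    big = tree.tip_tip_distances(endpoints=list(labels))
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = big[a, b]
    return out


def _pseudo_alignment(sequences: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Stack sequences pad-to-longest with terminal gaps (no realignment)."""
    labels = [n for n, _ in sequences]
    width = max(len(s) for _, s in sequences)
    mat = np.full((len(sequences), width), ord("-"), dtype=np.uint8)
    for i, (_, s) in enumerate(sequences):
        mat[i, :len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    return labels, mat


def _matrix_p_distance(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    gap = ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            valid = int(ok.sum())
            if valid == 0:
                d[i, j] = d[j, i] = 1.0
                continue
            same = int((mat[i][ok] == mat[j][ok]).sum())
            d[i, j] = d[j, i] = 1.0 - same / valid
    return d


def bootstrap_support(sequences: list[tuple[str, str]], B: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Columns of the stacked pseudo-alignment are resampled with replacement
    B times; each replicate's p-distance NJ tree votes for the internal
    bipartitions of the point-estimate tree.  Supports (0-100, integers)
    are stored as internal node names.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(sequences) < 4:
        raise ValueError("need >= 4 taxa for bootstrap supports")
    point = neighbor_joining(distance_matrix(sequences))
    labels, mat = _pseudo_alignment(sequences)
    rng = np.random.default_rng(seed)
    votes: dict[frozenset, int] = {b: 0 for b in tree_bipartitions(point)}
    width = mat.shape[1]
    for _ in range(B):
        cols = rng.integers(0, width, size=width)
        rep = mat[:, cols]
        dm = DistanceMatrix(_matrix_p_distance(rep), ids=labels)
        rep_bips = tree_bipartitions(neighbor_joining(dm))
        for b in votes:
            if b in rep_bips:
                votes[b] += 1
    taxa = frozenset(labels)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
            node.name = str(int(round(100.0 * votes[key] / B)))
    return point
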