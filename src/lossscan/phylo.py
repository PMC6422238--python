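"""CRD relatedness: pairwise global alignment identities, distance matrices,
neighbor-joining trees and Newick output.

Distances are simple identity distances, 1 - identity/100, where identity is
computed over aligned columns with no gap in either row. The NJ agglomeration
uses the standard Q-criterion with deterministic tie-breaking (the
lexicographically smallest label pair) and clamps negative branch lengths to
zero, flagging the tree when clamping occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .genemodels import ProtSequence


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment with its score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


def _make_aligner(substitution_table, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if substitution_table is None:
        substitution_table = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = substitution_table
    # biopython convention: open score applies to the first gap position
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    a,
    b,
    substitution_table=None,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment under affine gap scoring (BLOSUM62 by default).

    A gap of length L scores ``gap_open + (L-1) * gap_extend``. Identity is
    100 * (identical columns) / (columns where neither row is a gap).
    """
    sa = getattr(a, "residues", a)
    sb = getattr(b, "residues", b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(substitution_table, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    both = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    ident = sum(1 for x, y in both if x == y)
    identity_pct = 100.0 * ident / len(both) if both else 0.0
    return AlignmentResult(
        aligned_a=row_a, aligned_b=row_b, score=float(aln.score), identity_pct=identity_pct
    )


def identity_distance_matrix(sequences, **align_kwargs) -> DistanceMatrix:
    """Pairwise identity distances, d = 1 - identity/100, as a DistanceMatrix."""
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_global(seqs[i], seqs[j], **align_kwargs)
            d = 1.0 - res.identity_pct / 100.0
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


@dataclass
class PhyloTree:
    """An NJ tree over the distance-matrix labels; ``clamped`` flags whether any
    negative NJ branch length was clamped to zero."""

    tree: TreeNode
    clamped: bool = False

    def leaf_names(self) -> set:
        return {t.name for t in self.tree.tips()}

    def to_newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @staticmethod
    def from_newick(text: str) -> "PhyloTree":
        return PhyloTree(tree=TreeNode.read(StringIO(text), format="newick"))

    def tip_distances(self) -> DistanceMatrix:
        return self.tree.tip_tip_distances()


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining on an identity-distance matrix.

    Ties in the Q criterion are broken by the lexicographically lowest pair of
    clade labels (each clade keyed by its smallest leaf name); negative branch
    lengths are clamped to 0 and flagged on the returned tree.
    """
    if not isinstance(matrix, DistanceMatrix):
        data = np.asarray(matrix.data if hasattr(matrix, "data") else matrix, dtype=float)
        if not np.allclose(data, data.T):
            raise ValueError("distance matrix must be symmetric")
        matrix = DistanceMatrix(data)
    labels = list(matrix.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    D = {}
    nodes = {}
    keys = {}
    for i, li in enumerate(labels):
        nodes[li] = TreeNode(name=li)
        keys[li] = li
        for j, lj in enumerate(labels):
            if i != j:
                D[(li, lj)] = float(matrix[i, j])

    active = list(labels)
    clamped = False
    counter = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a in active:
            for b in active:
                if keys[a] >= keys[b]:
                    continue
                q = (m - 2) * D[(a, b)] - r[a] - r[b]
                cand = (q, keys[a], keys[b], a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _q, _ka, _kb, a, b = best
        d_ab = D[(a, b)]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d_ab - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        u = f"__internal{counter}"
        parent = TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.append(nodes[a])
        parent.append(nodes[b])
        nodes[u] = parent
        keys[u] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            d = 0.5 * (D[(a, c)] + D[(b, c)] - d_ab)
            D[(u, c)] = D[(c, u)] = d
        active = [c for c in active if c not in (a, b)]
        active.append(u)

    a, b = sorted(active, key=lambda x: keys[x])
    d = D[(a, b)]
    if d < 0:
        clamped = True
        d = 0.0
    # split the last edge at an (arbitrary) midpoint root; tip-to-tip path
    # lengths are independent of the split
    root = TreeNode(name=None)
    nodes[a].length = d / 2.0
    nodes[b].length = d / 2.0
    root.append(nodes[a])
    root.append(nodes[b])
    return PhyloTree(tree=root, clamped=clamped)


def write_distance_matrix(path, matrix: DistanceMatrix) -> None:
    """Square TSV with header row and column of labels."""
    import pandas as pd

    df = pd.DataFrame(matrix.data, index=list(matrix.ids), columns=list(matrix.ids))
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(c) for c in df.columns])
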