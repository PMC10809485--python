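"""Pairwise global comparison of protein-domain sequences.

Needleman–Wunsch with affine gap penalties under BLOSUM62, end gaps free —
the contract of EMBOSS Needle with its default penalties (gap open 10, gap
extend 0.5; an internal gap of length L costs open + extend·L).  Identity
and gap percentages are computed from the single reported alignment;
alignment % is defined as 100 − gap %.  The identity matrix is turned into
a dendrogram by agglomerative clustering of the distance 100 − identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PairwiseComparison",
    "global_align",
    "identity_matrix",
    "cluster_dendrogram",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PairwiseComparison:
    identity_pct: float
    gap_pct: float
    alignment_pct: float
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    # First gap position costs open+extend, later positions extend each, so
    # a length-L internal gap costs open + extend*L (the Needle convention).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # older end-gap attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseComparison:
    """Global alignment of two protein sequences with free end gaps.

    Statistics come from the single reported optimal alignment; the
    traceback is deterministic, so repeated calls agree.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"{name}: unknown residue letters {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    row_a, row_b = str(best[0]), str(best[1])
    length = len(row_a)
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    gaps = sum(1 for x, y in zip(row_a, row_b) if x == "-" or y == "-")
    identity_pct = 100.0 * identical / length
    gap_pct = 100.0 * gaps / length
    return PairwiseComparison(
        identity_pct=identity_pct,
        gap_pct=gap_pct,
        alignment_pct=100.0 - gap_pct,
        score=float(alignments.score),
        aligned_a=row_a,
        aligned_b=row_b,
    )


def identity_matrix(
    sequences: dict[str, str], **align_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric identity-% and alignment-% matrices over labelled sequences."""
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    ident = pd.DataFrame(100.0, index=labels, columns=labels)
    alnpct = pd.DataFrame(100.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            cmp = global_align(sequences[la], sequences[lb], **align_kwargs)
            ident.loc[la, lb] = ident.loc[lb, la] = cmp.identity_pct
            alnpct.loc[la, lb] = alnpct.loc[lb, la] = cmp.alignment_pct
    return ident, alnpct


def cluster_dendrogram(
    identity: pd.DataFrame, linkage: str = "average"
) -> tuple[str, np.ndarray]:
    """Agglomerative clustering of distance = 100 − identity; returns the
    newick string (branch lengths = half merge-height differences, so two
    items at distance d form a cherry with branch lengths d/2) and the
    scipy linkage matrix."""
    values = identity.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("identity matrix must be symmetric")
    if not np.allclose(np.diag(values), 100.0, atol=1e-9):
        raise ValueError("identity matrix diagonal must be 100")
    # Deterministic tie behaviour: reorder items lexicographically by label.
    order = sorted(range(len(identity)), key=lambda i: str(identity.index[i]))
    labels = [str(identity.index[i]) for i in order]
    dist = 100.0 - values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    heights = z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise ValueError("merge heights decreased; non-monotone linkage")
    tree = hierarchy.to_tree(z)
    # Branch length of an edge = (parent merge height - child height) / 2,
    # the ultrametric convention placing leaves at height 0.
    newick = _tree_newick(tree, labels) + ";"
    return newick, z


def _tree_newick(node, labels: list[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{(parent_dist) / 2:.6g}"
        left = rec(n.left, n.dist)
        right = rec(n.right, n.dist)
        a, b = sorted([left, right])
        return f"({a},{b}):{(parent_dist - n.dist) / 2:.6g}"

    if node.is_leaf():
        return labels[node.id]
    left = rec(node.left, node.dist)
    right = rec(node.right, node.dist)
    a, b = sorted([left, right])
    return f"({a},{b})"
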