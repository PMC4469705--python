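"""Distance phylogeny of number-coded barcodes.

The barcode distance is a normalized Hamming distance on the shared position
axis: positions with an ambiguity (unknown) in either barcode are excluded,
as are positions where both strains lack the pair (both code 8); a pair
present in one strain but absent in the other (8 vs non-8) counts as a
difference.  Trees are built with classic neighbor joining, deterministic
under a fixed input order (lowest row/column index breaks Q-matrix ties) and
with negative branch lengths clamped to zero (the clamped deficit is logged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .barcode import ABSENT_CODE, Barcode, UNKNOWN_CODE
from .errors import CrossReferenceError, UndefinedDistanceError, UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodeDistance:
    """Normalized Hamming distance between two code series."""

    value: float
    compared_positions: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise UsageError(f"distance {self.value} outside [0, 1]")


def barcode_distance(a: Barcode, b: Barcode) -> CodeDistance:
    """Fraction of differing positions among the comparable ones."""
    if len(a) != len(b):
        raise CrossReferenceError(
            f"barcodes {a.strain_id!r}/{b.strain_id!r} on different axes"
        )
    compared = differing = 0
    for ca, cb in zip(a.codes, b.codes):
        if ca == UNKNOWN_CODE or cb == UNKNOWN_CODE:
            continue
        if ca == ABSENT_CODE and cb == ABSENT_CODE:
            continue
        compared += 1
        if ca != cb:
            differing += 1
    if compared == 0:
        raise UndefinedDistanceError(
            f"no comparable positions between {a.strain_id!r} and {b.strain_id!r}"
        )
    return CodeDistance(differing / compared, compared)


def barcode_distance_matrix(barcodes: list[Barcode]) -> pd.DataFrame:
    ids = [b.strain_id for b in barcodes]
    n = len(barcodes)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = barcode_distance(barcodes[i], barcodes[j]).value
    return pd.DataFrame(mat, index=ids, columns=ids)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamped negative branch length %.6g at %s", length, context)
        return 0.0
    return length


def neighbor_joining(distances: pd.DataFrame) -> TreeNode:
    """Classic neighbor joining on a symmetric zero-diagonal matrix.

    Agglomerates the pair minimizing the Q criterion, breaking ties by the
    lowest (row, column) index in the current taxon order so that repeated
    runs give identical trees.  Returns an unrooted tree represented with a
    trifurcating root (for >3 taxa the last three lineages join the root).
    """
    ids = [str(x) for x in distances.index]
    if len(ids) < 3:
        raise UsageError(f"neighbor joining needs >=3 taxa, got {len(ids)}")
    mat = distances.to_numpy(dtype=float).copy()
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise UsageError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise UsageError("distance matrix must have a zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    labels = list(ids)

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = mat.sum(axis=1)
        q = (n - 2) * mat - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) wins ties: argmin scans in row-major order
        flat = int(np.argmin(q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = mat[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (n - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = _clamp(li, f"join({labels[i]},{labels[j]})")
        nodes[j].length = _clamp(lj, f"join({labels[i]},{labels[j]})")
        parent.append(nodes[i])
        parent.append(nodes[j])

        new_dist = 0.5 * (mat[i, :] + mat[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = new_dist[keep]
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [f"({labels[i]},{labels[j]})"]

    # closed-form three-point solution for the final trifurcation
    d_ab, d_ac, d_bc = mat[0, 1], mat[0, 2], mat[1, 2]
    root = TreeNode()
    for node, length in (
        (nodes[0], (d_ab + d_ac - d_bc) / 2),
        (nodes[1], (d_ab + d_bc - d_ac) / 2),
        (nodes[2], (d_ac + d_bc - d_ab) / 2),
    ):
        node.length = _clamp(length, "final trifurcation")
        root.append(node)
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, for topology comparison."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(min(side, all_tips - side, key=sorted))
    return splits
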