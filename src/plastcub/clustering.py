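"""Codon-usage clustering: RSCU distances, neighbor joining, heatmap order.

Taxa are compared by their 59-codon RSCU vectors. Neighbor joining
(Saitou & Nei) is implemented directly so the agglomeration order and
tie-breaks are fully deterministic: among equal Q values the pair with
the lexicographically smallest (label_i, label_j) is joined. Negative
branch-length estimates are clamped to zero (logged), as is standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RscuMatrix",
    "TaxonTree",
    "TreeNode",
    "rscu_distance",
    "neighbor_joining",
    "hierarchical_order",
]


@dataclass
class RscuMatrix:
    """Taxa x informative-codon RSCU values; NaN marks missing entries."""

    taxa: list[str]
    codons: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.codons)):
            raise ValueError("matrix shape does not match taxa x codons")


@dataclass
class TreeNode:
    """Tree node: leaves carry a label, internal nodes carry children with
    branch lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self, precision: int = 6) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return _quote(node.label or "")
            inner = ",".join(
                f"{render(c)}:{bl:.{precision}f}" for c, bl in node.children
            )
            return f"({inner})"

        return render(self) + ";"

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label or ""]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TaxonTree:
    """Unrooted tree over the input taxa (root is an arbitrary trifurcation)."""

    root: TreeNode

    def newick(self, precision: int = 6) -> str:
        return self.root.newick(precision=precision)

    def leaves(self) -> list[str]:
        return self.root.leaves()


def rscu_distance(matrix: RscuMatrix, metric: str = "euclidean") -> np.ndarray:
    """Symmetric taxon-by-taxon distance matrix from RSCU profiles.

    Missing entries are handled pairwise-complete: each pair is compared
    over the codons defined in both profiles. Metrics: ``euclidean`` or
    ``correlation`` (1 - Pearson).
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    v = matrix.values
    nt = len(matrix.taxa)
    if nt < 2:
        raise ValueError("need >= 2 taxa")
    for i, t in enumerate(matrix.taxa):
        if np.isnan(v[i]).all():
            raise ValueError(f"taxon {t!r} has an all-missing profile")
    dist = np.zeros((nt, nt))
    for i in range(nt):
        for j in range(i + 1, nt):
            mask = ~(np.isnan(v[i]) | np.isnan(v[j]))
            if not mask.any():
                raise ValueError(
                    f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no codons"
                )
            a, b = v[i, mask], v[j, mask]
            if metric == "euclidean":
                d = float(np.sqrt(((a - b) ** 2).sum()))
            else:
                if a.std() == 0 or b.std() == 0:
                    d = 0.0 if np.allclose(a, b) else 1.0
                else:
                    d = float(1.0 - np.corrcoef(a, b)[0, 1])
            dist[i, j] = dist[j, i] = d
    return dist


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> TaxonTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Exact on additive distance matrices; deterministic tie-break by the
    smallest (label_i, label_j) pair; negative branch lengths clamped to 0.
    """
    d = np.asarray(dist, dtype=float)
    labels = list(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    # sort key for tie-breaks: (min leaf label under node)
    keys: list[str] = list(labels)
    D = d.copy()

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.info("clamping negative NJ branch length %.6g (%s)", x, what)
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        best = None  # (q, key_i, key_j, i, j)
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - R[i] - R[j]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (q, ki, kj, i, j)
                if best is None or (q < best[0] - 1e-12) or (
                    abs(q - best[0]) <= 1e-12 and (ki, kj) < (best[1], best[2])
                ):
                    best = cand
        _, _, _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[
            (nodes[i], clamp(li, keys[i])), (nodes[j], clamp(lj, keys[j])),
        ])
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_row[keep]])
        D = np.column_stack([D, np.append(new_row[keep], 0.0)])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # resolve the final three nodes with the three-point formulas
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode(children=[
        (nodes[a], clamp(la, keys[a])),
        (nodes[b], clamp(lb, keys[b])),
        (nodes[c], clamp(lc, keys[c])),
    ])
    return TaxonTree(root=root)


def hierarchical_order(
    matrix: RscuMatrix, linkage: str = "average"
) -> tuple[list[int], list[int]]:
    """Deterministic dendrogram leaf orderings for heatmap export.

    Returns (row order over taxa, column order over codons) from
    average-linkage (by default) hierarchical clustering of euclidean
    distances; missing entries are filled with the column mean for the
    ordering only.
    """
    v = matrix.values.copy()
    col_means = np.nanmean(np.where(np.isnan(v), np.nan, v), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    inds = np.where(np.isnan(v))
    v[inds] = np.take(col_means, inds[1])

    def order(mat: np.ndarray) -> list[int]:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        dm = squareform(
            np.sqrt(((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)),
            checks=False,
        )
        Z = hierarchy.linkage(dm, method=linkage)
        return [int(i) for i in hierarchy.leaves_list(Z)]

    return order(v), order(v.T)
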