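"""Neighbor joining, tree utilities, and reference-based clade assignment.

Classic Saitou–Nei agglomerative NJ: at each step join the pair (i, j)
minimizing Q(i, j) = (n − 2) d(i, j) − r_i − r_j, assign pendant branch
lengths from the NJ formulas, collapse the pair, and finish with the
three-taxon closed form.  The result is an unrooted binary tree,
represented here with a degree-3 "root" placeholder.

Queries are classified against biochemically characterized references by
the smallest edge-bounded clade rule: a query takes the label of the
smallest bipartition side that contains it together with at least one
reference, provided all references inside carry a single label;
otherwise it is left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import logging

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(eq=False)
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def postorder(self) -> list["TreeNode"]:
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.postorder())
        out.append(self)
        return out

    def to_newick(self) -> str:
        return _newick(self) + ";"


def _newick(node: TreeNode) -> str:
    if node.is_leaf():
        label = node.name or ""
        return f"{label}:{node.length:.10g}"
    inner = ",".join(_newick(c) for c in node.children)
    if node.length or node.name:
        return f"({inner}){node.name or ''}:{node.length:.10g}"
    return f"({inner})"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an ordered taxon list."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match taxa")
        if np.isnan(self.values).any():
            raise DataError("distance matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t", index_label="taxon"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(taxa=[str(t) for t in frame.columns], values=frame.to_numpy())


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic lexicographic tie-break."""
    n = len(dist.taxa)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dist.taxa]
    d = dist.values.astype(float).copy()

    n_clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q(i,j) = (m-2) d_ij - r_i - r_j ; first minimum in (i, j) order
        best = (0, 1)
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            n_clamped += 1
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new node to the others
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in keep])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [new]

    # 3-node closed form
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        if length < 0:
            n_clamped += 1
            length = 0.0
        node.length = length
    if n_clamped:
        logger.warning("clamped %d negative branch length(s) to 0", n_clamped)
    return TreeNode(children=list(nodes))


def tree_to_distances(
    tree: TreeNode, taxa: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """Pairwise path-length matrix of a tree's leaves."""
    order = list(taxa) if taxa is not None else sorted(tree.leaf_names())
    index = {t: k for k, t in enumerate(order)}
    n = len(order)
    d = np.zeros((n, n))
    # at each internal node, pairs split across distinct children meet there
    below: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[id(node)] = {node.name: 0.0}
        else:
            merged: dict[str, float] = {}
            child_maps = [
                {t: dist + c.length for t, dist in below[id(c)].items()}
                for c in node.children
            ]
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for ta, da in child_maps[a].items():
                        for tb, db in child_maps[b].items():
                            d[index[ta], index[tb]] = da + db
                            d[index[tb], index[ta]] = da + db
                merged.update(child_maps[a])
            merged.update(child_maps[-1])
            below[id(node)] = merged
    return DistanceMatrix(taxa=order, values=d)


def _bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf set below each non-root node (one side of each edge)."""
    sides = []
    for node in tree.postorder():
        if node is tree:
            continue
        sides.append(frozenset(node.leaf_names()))
    return sides


def is_monophyletic(tree: TreeNode, taxa_subset: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly this leaf subset."""
    subset = frozenset(taxa_subset)
    all_leaves = frozenset(tree.leaf_names())
    unknown = subset - all_leaves
    if unknown:
        raise DataError(f"unknown taxa: {sorted(unknown)}")
    if subset == all_leaves or len(subset) == 1:
        return True
    for side in _bipartitions(tree):
        if side == subset or (all_leaves - side) == subset:
            return True
    return False


def assign_by_clade(
    tree: TreeNode,
    reference_labels: Mapping[str, str],
    queries: Optional[Iterable[str]] = None,
) -> dict[str, str]:
    """Label queries by the smallest edge-bounded clade holding a reference.

    A clade whose references carry more than one label leaves the query
    ``unassigned``.  Deterministic: clades considered smallest-first, ties
    broken by sorted leaf content.
    """
    if not reference_labels:
        raise ParameterError("at least one labelled reference is required")
    all_leaves = frozenset(tree.leaf_names())
    missing = set(reference_labels) - all_leaves
    if missing:
        raise DataError(f"reference taxa absent from tree: {sorted(missing)}")
    query_set = (
        sorted(all_leaves - set(reference_labels))
        if queries is None
        else sorted(queries)
    )
    refs = set(reference_labels)
    clades: set[frozenset[str]] = set()
    for side in _bipartitions(tree):
        clades.add(side)
        clades.add(all_leaves - side)
    ordered = sorted(clades, key=lambda c: (len(c), tuple(sorted(c))))
    assignment: dict[str, str] = {}
    for q in query_set:
        if q not in all_leaves:
            raise DataError(f"query taxon {q!r} absent from tree")
        label = UNASSIGNED
        for clade in ordered:
            if q not in clade:
                continue
            inside = refs & clade
            if not inside:
                continue
            labels = {reference_labels[r] for r in inside}
            label = labels.pop() if len(labels) == 1 else UNASSIGNED
            break
        assignment[q] = label
    return assignment
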