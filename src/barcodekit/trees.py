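"""Distance-based tree building (NJ, UPGMA) and tree metrics.

Neighbor joining follows the Saitou-Nei agglomeration with the Q-matrix
criterion; negative branch-length estimates are clamped to zero with the
deficit moved to the sister branch, so reconstruction is exact on additive
matrices.  UPGMA is average-linkage agglomeration and is ultrametric by
construction.  Newick parsing/serialisation and patristic path sums are
delegated to dendropy behind the :class:`PhyloTree` surface.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from .distances import DistanceMatrix, distance_matrix
from .errors import SaturatedDistanceError, TreeError

_NEEDS_QUOTE = re.compile(r"[\s(),:;'\[\]]")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A rooted or unrooted tree with branch lengths, tips labelled by specimen id.

    Thin wrapper around a :class:`dendropy.Tree`.  A tree parsed from newick is
    treated as rooted when its root is bifurcating (or carries an explicit
    ``[&R]`` token) and unrooted when the root is a basal polytomy.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._t = dtree
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "internal node"
                raise TreeError(f"negative branch length on edge above {name!r}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                rooting="default-rooted",
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed newick: {exc}") from exc
        tree = cls(dtree)
        if rooted is None:
            rooted = len(dtree.seed_node.child_nodes()) <= 2
        dtree.is_rooted = bool(rooted)
        return tree

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    # -- serialisation ------------------------------------------------------

    def to_newick(self) -> str:
        s = self._t.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        return s.strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- basic structure ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def is_rooted(self) -> bool:
        return bool(self._t.is_rooted)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._t.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        out = {}
        for leaf in self._t.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def node_heights(self) -> dict[dendropy.Node, float]:
        """Height of every node = max path length to a descendant tip."""
        heights: dict[dendropy.Node, float] = {}
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                heights[node] = 0.0
            else:
                heights[node] = max(
                    heights[c] + (c.edge.length or 0.0) for c in node.child_nodes()
                )
        return heights

    def midpoint_rooted(self) -> "PhyloTree":
        """A rooted copy of this tree, rooted at the midpoint of the longest path."""
        clone = self._t.clone(depth=1)
        clone.reroot_at_midpoint(update_bipartitions=False)
        clone.is_rooted = True
        return PhyloTree(clone)


def _check_finite(dm: DistanceMatrix) -> None:
    bad = dm.saturated_pairs
    if bad:
        raise SaturatedDistanceError(
            f"infinite distances for pairs: {bad}; exclude saturated pairs first"
        )


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Exact on additive matrices.  Negative branch-length estimates are clamped
    to zero and the deficit moved to the adjacent branch of the joined pair.
    Ties in the Q criterion are broken by the smallest (row, column) index
    pair, so results are deterministic.
    """
    n = len(dm)
    if n < 3:
        raise TreeError(f"neighbor joining needs at least 3 taxa, got {n}")
    _check_finite(dm)
    D = dm.values.astype(float).copy()
    sub = [_quote(i) for i in dm.ids]
    while len(sub) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0.0:
            li, lj = 0.0, d_ij
        elif lj < 0.0:
            li, lj = d_ij, 0.0
        joined = f"({sub[i]}:{li:.12g},{sub[j]}:{lj:.12g})"
        dk = np.maximum(0.5 * (D[i, :] + D[j, :] - d_ij), 0.0)
        keep = [k for k in range(m) if k != i and k != j]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        sub = [sub[k] for k in keep] + [joined]
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    newick = f"({sub[0]}:{l0:.12g},{sub[1]}:{l1:.12g},{sub[2]}:{l2:.12g});"
    return PhyloTree.from_newick(newick, rooted=False)


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; returns a rooted ultrametric tree."""
    n = len(dm)
    if n < 2:
        raise TreeError(f"UPGMA needs at least 2 taxa, got {n}")
    _check_finite(dm)
    Z = linkage(dm.condensed(), method="average")
    heights = {k: 0.0 for k in range(n)}
    sub = {k: _quote(dm.ids[k]) for k in range(n)}
    for step, (a, b, h, _count) in enumerate(Z):
        a, b = int(a), int(b)
        node_h = h / 2.0  # linkage heights are inter-cluster distances
        k = n + step
        la, lb = node_h - heights[a], node_h - heights[b]
        sub[k] = f"({sub[a]}:{la:.12g},{sub[b]}:{lb:.12g})"
        heights[k] = node_h
    return PhyloTree.from_newick(sub[2 * n - 2] + ";", rooted=True)


def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the unique path between every pair of tips."""
    dtree = tree.dendropy_tree
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "an internal node"
            raise TreeError(f"missing branch length on the edge above {name}")
    pdm = dtree.phylogenetic_distance_matrix()
    leaves = list(dtree.leaf_node_iter())
    ids = [lf.taxon.label for lf in leaves]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, model="patristic")


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Whether all root-to-tip depths agree within *rel_tol* (relative).

    Returns ``(flag, max_relative_deviation)``.  Requires a rooted tree.
    """
    if not tree.is_rooted:
        raise TreeError("ultrametricity is defined only for rooted trees")
    depths = np.array(list(tree.depths().values()))
    dmax = float(depths.max())
    if dmax == 0.0:
        return True, 0.0
    dev = float((depths.max() - depths.min()) / dmax)
    return dev <= rel_tol, dev


def _bipartitions(tree: PhyloTree) -> dict[int, frozenset]:
    """Internal dendropy nodes -> canonical bipartition (smaller tip side)."""
    all_tips = frozenset(tree.tip_labels)
    out = {}
    tips_below: dict[dendropy.Node, frozenset] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = frozenset([node.taxon.label])
        else:
            below = frozenset().union(*(tips_below[c] for c in node.child_nodes()))
            tips_below[node] = below
            if node.parent_node is not None and 1 < len(below) < len(all_tips) - 1:
                other = all_tips - below
                canon = min(below, other, key=lambda s: (len(s), sorted(s)))
                out[id(node)] = canon
    return out


def nj_bootstrap_support(aln, model: str = "ndiff", n_reps: int = 100, seed: int = 0):
    """NJ tree with column-resampling bootstrap support on internal nodes.

    Support values are advisory only (no decision rule in this package
    conditions on them); they annotate internal node labels as integer
    percentages.  Returns ``(tree, support)`` where *support* maps canonical
    bipartitions to percentages.
    """
    rng = np.random.default_rng(seed)
    base = neighbor_joining(distance_matrix(aln, model=model))
    counts: dict[frozenset, int] = {}
    L = aln.alignment_length
    from .io import BarcodeAlignment

    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        seqs = ["".join(s[c] for c in cols) for s in aln.seqs]
        rep = BarcodeAlignment(
            ids=list(aln.ids), seqs=seqs, records=aln.records, marker=aln.marker
        )
        rep_tree = neighbor_joining(distance_matrix(rep, model=model))
        for bip in set(_bipartitions(rep_tree).values()):
            counts[bip] = counts.get(bip, 0) + 1
    support = {bip: round(100.0 * c / n_reps) for bip, c in counts.items()}
    bips = _bipartitions(base)
    for node in base.dendropy_tree.preorder_node_iter():
        if id(node) in bips:
            node.label = str(support.get(bips[id(node)], 0))
    return base, support
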