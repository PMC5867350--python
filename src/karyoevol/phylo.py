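"""Rooted phylogenies: newick I/O, pruning, Grafen lengths, UPGMA.

The tree container is deliberately small — a rooted node hierarchy with
optional labels and branch lengths — because every downstream computation
(Brownian-motion reconstruction, chromosome-number Markov chains, branch
event annotation) walks the tree directly.  Newick parsing is delegated to
dendropy; writing uses a canonical formatter so that round-trips are
byte-stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import dendropy
import numpy as np

from .karyotypes import DivergenceMatrix

__all__ = [
    "TreeNode",
    "Phylogeny",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "grafen_lengths",
    "is_ultrametric",
    "upgma",
]


@dataclass
class TreeNode:
    name: str | None = None
    parent_edge_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class Phylogeny:
    """A rooted tree with unique leaf names and optional branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        names = [leaf.name for leaf in self.root.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.root.preorder():
            if node.parent_edge_length is not None and node.parent_edge_length < 0:
                raise ValueError(f"negative branch length at {node.name!r}")

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def find(self, name: str) -> TreeNode:
        for node in self.root.preorder():
            if node.name == name:
                return node
        raise KeyError(name)

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named leaves."""
        target = set(names)
        unknown = target - set(self.leaf_names)
        if unknown:
            raise KeyError(f"unknown leaves: {sorted(unknown)}")
        for node in self.root.postorder():
            if target <= {leaf.name for leaf in node.leaves()}:
                return node
        raise AssertionError("unreachable: root covers all leaves")

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by id(node); missing lengths error."""
        out: dict[int, float] = {id(self.root): 0.0}
        for node in self.root.preorder():
            if node is self.root:
                continue
            if node.parent_edge_length is None:
                raise ValueError(f"missing branch length above {node.name!r}")
            out[id(node)] = out[id(node.parent)] + node.parent_edge_length
        return out

    def copy(self) -> "Phylogeny":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, parent_edge_length=node.parent_edge_length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))

    def __repr__(self) -> str:
        return f"Phylogeny({self.n_leaves} leaves)"


# --- Newick I/O -----------------------------------------------------------


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = TreeNode(name=label, parent_edge_length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a newick string or file into a :class:`Phylogeny`.

    Internal node labels (written after the closing parenthesis) are kept;
    underscores in unquoted labels are preserved verbatim.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(") and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    return Phylogeny(_from_dendropy(dtree.seed_node))


def _format_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        out = "(" + ",".join(_node_newick(c) for c in node.children) + ")"
        if node.name:
            out += node.name
    if node.parent_edge_length is not None:
        out += f":{_format_length(node.parent_edge_length)}"
    return out


def write_newick(tree: Phylogeny, path: str | Path | None = None) -> str:
    """Serialise to canonical newick (labels after parentheses, 10 s.f. lengths)."""
    text = _node_newick(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# --- Pruning --------------------------------------------------------------


def prune_to_taxa(tree: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    """Restrict to the named leaves, collapsing unary nodes (lengths summed)."""
    keep_set = set(keep)
    unknown = keep_set - set(tree.leaf_names)
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep_set) < 2:
        raise ValueError("need at least 2 taxa after pruning")

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.name in keep_set:
                return TreeNode(name=node.name, parent_edge_length=node.parent_edge_length)
            return None
        kept = [c for c in (prune(child) for child in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # collapse unary node: absorb this edge into the surviving child
            child = kept[0]
            if node.parent_edge_length is not None and child.parent_edge_length is not None:
                child.parent_edge_length += node.parent_edge_length
            elif node.parent_edge_length is not None:
                child.parent_edge_length = node.parent_edge_length
            return child
        new = TreeNode(name=node.name, parent_edge_length=node.parent_edge_length)
        for c in kept:
            new.add_child(c)
        return new

    root = prune(tree.root)
    assert root is not None
    # a pruned root keeps no pendant edge
    if not root.is_leaf:
        root.parent_edge_length = None
    return Phylogeny(root)


# --- Grafen branch lengths ------------------------------------------------


def grafen_lengths(tree: Phylogeny, rho: float = 1.0) -> Phylogeny:
    """Assign ultrametric branch lengths from descendant-leaf counts.

    Each node gets height ((k - 1) / (n - 1)) ** rho where k is its number
    of descendant leaves and n the total leaf count; leaves sit at height 0
    and the root at exactly 1.  Branch length = parent height - own height.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    out = tree.copy()
    n = out.n_leaves
    if n < 2:
        raise ValueError("need at least 2 leaves")
    heights: dict[int, float] = {}
    for node in out.root.postorder():
        k = len(node.leaves())
        heights[id(node)] = ((k - 1) / (n - 1)) ** rho if k > 1 else 0.0
    for node in out.root.preorder():
        if node is out.root:
            node.parent_edge_length = None
        else:
            node.parent_edge_length = heights[id(node.parent)] - heights[id(node)]
    return out


def is_ultrametric(tree: Phylogeny, tolerance: float = 1e-8) -> bool:
    """True iff all root-to-leaf path lengths agree within ``tolerance``."""
    depths = tree.depths()
    leaf_depths = [depths[id(leaf)] for leaf in tree.root.leaves()]
    return max(leaf_depths) - min(leaf_depths) <= tolerance


# --- UPGMA ----------------------------------------------------------------


def upgma(matrix: DivergenceMatrix, euclidean_rows: bool = False) -> Phylogeny:
    """Average-linkage (UPGMA) dendrogram from a distance matrix.

    Clusters are merged at height d/2 so leaf heights are 0 and the output
    is ultrametric by construction.  Ties are broken by merging the
    lexicographically smallest taxon pair among the minima, making the
    topology deterministic.  With ``euclidean_rows`` the matrix rows are
    first treated as coordinates and pairwise Euclidean row distances are
    clustered instead (the matrix-as-feature-vector reading of
    "UPGMA based on Euclidean distance").
    """
    names = list(matrix.taxa)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = np.array(matrix.values, dtype=float)
    if euclidean_rows:
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(matrix.values, metric="euclidean"))

    clusters: dict[int, TreeNode] = {}
    sizes: dict[int, int] = {}
    heights: dict[int, float] = {}
    labels: dict[int, str] = {}
    dist: dict[frozenset[int], float] = {}
    for i, name in enumerate(names):
        clusters[i] = TreeNode(name=name)
        sizes[i] = 1
        heights[i] = 0.0
        labels[i] = name
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d[i, j]

    next_id = n
    active = set(range(n))
    while len(active) > 1:
        # find minimum-distance pair; tie-break on sorted label pair
        best = min(
            (dist[frozenset((i, j))], tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in itertools.combinations(sorted(active), 2)
        )
        dmin, _, i, j = best
        h = dmin / 2.0
        parent = TreeNode()
        for cid in (i, j):
            child = clusters[cid]
            child.parent_edge_length = h - heights[cid]
            parent.add_child(child)
        clusters[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        for k in active:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dist.pop(frozenset((i, j)), None)
        active.add(next_id)
        next_id += 1

    (root_id,) = active
    return Phylogeny(clusters[root_id])
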