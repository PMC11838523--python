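"""Phylogenetic trees: Newick IO (via dendropy) and an array-indexed view
used by the pruning likelihood engine."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


class NewickError(ValueError):
    pass


@dataclass
class PhyloTree:
    """A rooted or unrooted gene tree with branch lengths in expected
    substitutions per nucleotide site.

    Wraps a :class:`dendropy.Tree`; the likelihood engine consumes the
    flattened index arrays (postorder node order, per-node parent and edge
    length).  For time-reversible models the (arbitrary) rooting at the
    Newick seed node does not affect the likelihood.
    """

    dtree: dendropy.Tree

    # --- IO -------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        if not dtree.leaf_nodes():
            raise NewickError("tree has no leaves")
        return cls(dtree=dtree)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # --- structure ------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.dtree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.dtree.leaf_nodes())

    def copy(self) -> "PhyloTree":
        return PhyloTree(dtree=self.dtree.clone(depth=1))

    def reroot_at_leaf_edge(self, leaf_name: str, fraction: float = 0.5) -> "PhyloTree":
        """Reroot on the edge above a named leaf (pulley-principle checks)."""
        t = self.dtree.clone(depth=1)
        node = next(l for l in t.leaf_node_iter() if l.taxon.label == leaf_name)
        edge = node.edge
        t.reroot_at_edge(edge, length1=edge.length * (1 - fraction),
                         length2=edge.length * fraction)
        return PhyloTree(dtree=t)

    def index(self, leaf_order: list[str]) -> "TreeIndex":
        return TreeIndex.build(self, leaf_order)


@dataclass
class TreeIndex:
    """Flattened tree arrays for pruning.

    Nodes are numbered so that the first ``n_leaves`` ids map to
    ``leaf_order``; ``postorder`` lists internal node ids children-first;
    ``children[i]`` are the child ids of node ``i``; ``edge_length[i]`` is
    the branch above node ``i`` (undefined for the root).  Branch ids for
    optimization are node ids of all non-root nodes.
    """

    n_leaves: int
    n_nodes: int
    root: int
    postorder: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    branch_nodes: np.ndarray  # non-root node ids, i.e. one per branch

    @classmethod
    def build(cls, tree: PhyloTree, leaf_order: list[str]) -> "TreeIndex":
        leaf_id = {name: i for i, name in enumerate(leaf_order)}
        missing = set(tree.leaf_names) - set(leaf_order)
        if missing:
            raise ValueError(f"tree leaves not present in alignment: {sorted(missing)}")
        n_leaves = tree.n_leaves
        nodes = list(tree.dtree.postorder_node_iter())
        ids: dict[int, int] = {}
        next_internal = n_leaves
        for node in nodes:
            if node.is_leaf():
                ids[id(node)] = leaf_id[node.taxon.label]
            else:
                ids[id(node)] = next_internal
                next_internal += 1
        n_nodes = next_internal
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        edge_length = np.zeros(n_nodes)
        postorder = []
        root = ids[id(tree.dtree.seed_node)]
        for node in nodes:
            nid = ids[id(node)]
            if not node.is_leaf():
                children[nid] = [ids[id(c)] for c in node.child_nodes()]
                postorder.append(nid)
            edge_length[nid] = node.edge.length if node.edge.length is not None else 0.0
        branch_nodes = np.array([i for i in range(n_nodes) if i != root], dtype=int)
        return cls(
            n_leaves=n_leaves,
            n_nodes=n_nodes,
            root=root,
            postorder=np.array(postorder, dtype=int),
            children=children,
            edge_length=edge_length,
            branch_nodes=branch_nodes,
        )

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)


def parse_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()
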