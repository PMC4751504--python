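"""Lightweight phylogenetic tree container used by the NJ/bootstrap machinery.

Trees are held as simple parent/child node records; the unrooted NJ tree is
represented with a trifurcating root.  Serialization (Newick) and topological
comparison (Robinson-Foulds) delegate to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = ["TreeNode", "PhyloTree"]


@dataclass(eq=False)
class TreeNode:
    """A node of a :class:`PhyloTree`.

    ``length`` is the branch length of the edge above the node (clamped to be
    non-negative); ``raw_length`` keeps the unclamped value NJ produced.
    ``support`` is an integer bootstrap count out of ``PhyloTree.n_bootstrap``.
    """

    label: Optional[str] = None
    length: float = 0.0
    raw_length: float = 0.0
    support: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


@dataclass
class PhyloTree:
    root: TreeNode
    n_bootstrap: Optional[int] = None

    # -- basic queries -----------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def __len__(self) -> int:
        return len(self.leaf_labels())

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each bipartition is canonicalized as the side *not* containing the
        lexicographically smallest leaf label, and maps back to the child node
        whose subtree is that side.
        """
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def below(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            got = frozenset().union(*(below(c) for c in node.children))
            if node is not self.root:
                side = got if ref not in got else all_leaves - got
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out[side] = node
            return got

        below(self.root)
        return out

    def clades(self) -> dict[TreeNode, frozenset]:
        """Leaf-label set below every node (the root maps to all leaves)."""
        out: dict[TreeNode, frozenset] = {}

        def below(node: TreeNode) -> frozenset:
            if node.is_leaf:
                got = frozenset([node.label])
            else:
                got = frozenset().union(*(below(c) for c in node.children))
            out[node] = got
            return got

        below(self.root)
        return out

    # -- dendropy bridge ---------------------------------------------------

    def to_dendropy(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
        tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def build(node: TreeNode, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length
            if node.is_leaf:
                dnode.taxon = tns.require_taxon(label=node.label)
            else:
                if node.support is not None:
                    dnode.label = str(node.support)
                for c in node.children:
                    build(c, dnode.new_child())

        build(self.root, dtree.seed_node)
        dtree.seed_node.edge.length = None
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        def build(dnode: dendropy.Node) -> TreeNode:
            node = TreeNode()
            if dnode.edge.length is not None:
                node.length = float(dnode.edge.length)
                node.raw_length = node.length
            if dnode.is_leaf():
                node.label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            else:
                if dnode.label is not None:
                    try:
                        node.support = int(dnode.label)
                    except ValueError:
                        pass
                node.children = [build(c) for c in dnode.child_nodes()]
            return node

        return cls(root=build(dtree.seed_node))

    def to_newick(self) -> str:
        dtree = self.to_dendropy()
        s = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".6f",
        )
        return s.strip() + "\n"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree)

    # -- comparison --------------------------------------------------------

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unweighted Robinson-Foulds distance (symmetric bipartition difference)."""
        a = set(self.bipartitions())
        b = set(other.bipartitions())
        return len(a ^ b)
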