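"""Rooted species tree with stable branch labels.

The study design fixes a rooted 10-taxon topology: chicken and platypus as
successive outgroups, two marsupials (opossum, Tasmanian devil) and six
eutherians (mouse plus five catarrhine primates).  Every branch carries a
stable label — terminal branches are named by their leaf, internal branches
by the clade whose stem they form (``Theria_stem`` is the branch from the
mammalian ancestor down to the therian ancestor, etc.).  Gain/loss mapping
and stem dN/dS both address branches through these labels.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Mapping, Optional

import dendropy

__all__ = ["TreeNode", "SpeciesTree", "DEFAULT_SPECIES_TREE_NEWICK"]

#: Fixed study topology.  Internal node labels name the branch above the node.
DEFAULT_SPECIES_TREE_NEWICK = (
    "(chicken,(platypus,((opossum,tasmanian_devil)Marsupialia_stem,"
    "(mouse,(macaque,(gorilla,(human,(chimpanzee,bonobo)Pan_stem)"
    "Hominini_stem)Homininae_stem)Catarrhini_stem)Eutheria_stem)"
    "Theria_stem)Mammalia_stem)root;"
)


class TreeNode:
    """One node; ``label`` doubles as the label of the branch above it."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r})"


class SpeciesTree:
    """Rooted tree addressed by branch label.

    Parameters
    ----------
    root:
        Root :class:`TreeNode`; all nodes must carry unique labels.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._by_label: Dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.label in self._by_label:
                raise ValueError(f"duplicate branch label {node.label!r}")
            self._by_label[node.label] = node
        self._leaves: List[str] = [n.label for n in self.postorder() if n.is_leaf]

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        counter = [0]

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            else:
                counter[0] += 1
                label = f"node{counter[0]}"
            node = TreeNode(label, dnode.edge.length)
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def default(cls) -> "SpeciesTree":
        """The fixed 10-species study topology."""
        return cls.from_newick(DEFAULT_SPECIES_TREE_NEWICK)

    # -- queries -----------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    @property
    def leaf_names(self) -> List[str]:
        return list(self._leaves)

    @property
    def branch_labels(self) -> List[str]:
        return [n.label for n in self.preorder()]

    def node(self, label: str) -> TreeNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown branch label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def subtree_leaves(self, label: str) -> List[str]:
        """Leaves descending from (and including) the labelled branch."""
        node = self.node(label)
        return [n.label for n in _walk_leaves(node)]

    def mrca(self, leaves: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the given leaves."""
        wanted = list(leaves)
        if not wanted:
            raise ValueError("mrca of an empty leaf set is undefined")
        paths = []
        for name in wanted:
            node = self.node(name)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        assert mrca is not None
        return mrca

    def clade_leaves(self, clade: str) -> List[str]:
        """Leaves of a named clade; accepts either ``X`` or ``X_stem``."""
        if clade in self._by_label:
            return self.subtree_leaves(clade)
        stem = f"{clade}_stem"
        if stem in self._by_label:
            return self.subtree_leaves(stem)
        raise KeyError(f"no clade or stem branch named {clade!r}")

    # -- mutation / output -------------------------------------------------

    def set_branch_lengths(self, lengths: Mapping[str, float]) -> "SpeciesTree":
        for label, length in lengths.items():
            if length < 0:
                raise ValueError(f"negative branch length for {label!r}")
            self.node(label).length = float(length)
        return self

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){node.label}"
            if node.length is not None:
                body += f":{node.length:g}"
            return body

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _walk_leaves(node: TreeNode) -> Iterator[TreeNode]:
    if node.is_leaf:
        yield node
    else:
        for child in node.children:
            yield from _walk_leaves(child)
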