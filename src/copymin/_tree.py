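"""Lightweight rooted-tree structure shared by all modules.

Gene trees here are rooted, possibly multifurcating trees whose leaves
carry gene identifiers and (after annotation) species codes, and whose
internal nodes may carry a bootstrap support on the 0-100 scale. The
structure is deliberately minimal: dendropy handles Newick I/O (see
``tree_io``) and is converted to/from this representation at the border.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional


class TreeNode:
    """A node in a :class:`GeneTree`.

    Attributes
    ----------
    children : list[TreeNode]
    parent : TreeNode or None
    label : str or None
        Gene identifier for leaves; an optional name for internal nodes
        (internal labels that parse as numbers are supports, not names).
    support : float or None
        Bootstrap support in [0, 100]; ``None`` means absent, which all
        operations treat as fully supported.
    length : float or None
        Branch length of the edge above this node.
    species : str or None
        Species code attached by ``tree_io.assign_taxa``.
    """

    __slots__ = ("children", "parent", "label", "support", "length", "species")

    def __init__(self, label=None, support=None, length=None, species=None):
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.label = label
        self.support = support
        self.length = length
        self.species = species

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    def iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator["TreeNode"]:
        # iterative to keep deep simulated trees safe
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.iter_preorder() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {n.label for n in self.leaves()}

    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.support, self.length, self.species)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} label={self.label!r} support={self.support!r}>"


class GeneTree:
    """A rooted gene-family tree with supports on internal nodes."""

    def __init__(self, root: TreeNode):
        self.root = root
        #: free-form flags set by operations (e.g. ``outgroup_clean``)
        self.meta: dict = {}

    # -- traversal ---------------------------------------------------------
    def iter_nodes(self, order: str = "preorder") -> Iterator[TreeNode]:
        if order == "preorder":
            return self.root.iter_preorder()
        if order == "postorder":
            return self.root.iter_postorder()
        raise ValueError(f"unknown traversal order: {order!r}")

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> set[str]:
        return self.root.leaf_labels()

    def internal_nodes(self, include_root: bool = True) -> list[TreeNode]:
        nodes = [n for n in self.iter_nodes() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def n_internal_edges(self) -> int:
        """Number of internal edges (edges whose child end is internal)."""
        return len(self.internal_nodes(include_root=False))

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"leaf {label!r} not found in tree")

    def copy(self) -> "GeneTree":
        new = GeneTree(self.root.copy())
        new.meta = dict(self.meta)
        return new

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        labels = [n.label for n in self.leaves()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.iter_nodes():
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise ValueError(
                    f"support {node.support} outside [0, 100] at node {node.label!r}"
                )
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length at node {node.label!r}")

    def topology_key(self) -> frozenset:
        """Multiset-free key of the rooted topology: the set of leaf-label
        sets of all internal nodes (plus the full leaf set). Two trees with
        the same key have identical rooted topologies over the same leaves."""
        return frozenset(
            frozenset(n.leaf_labels()) for n in self.iter_nodes() if not n.is_leaf
        )

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each encoded by the smaller-or-
        canonical side's leaf set. Used to check that rooting is topology-
        preserving."""
        all_leaves = frozenset(self.leaf_labels())
        parts = set()
        for node in self.iter_nodes():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_labels())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue  # pendant or trivial split
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return parts

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<GeneTree with {len(self.leaves())} leaves>"


def mrca_node(root: TreeNode, labels: set[str]) -> TreeNode:
    """Lowest node of the subtree at ``root`` whose leaf set covers ``labels``."""
    if not labels:
        raise ValueError("mrca of an empty leaf set is undefined")
    missing = labels - root.leaf_labels()
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    node = root
    while True:
        covering = [c for c in node.children if labels <= c.leaf_labels()]
        if len(covering) == 1:
            node = covering[0]
        else:
            return node


def filter_nodes(root: TreeNode, pred: Callable[[TreeNode], bool]) -> list[TreeNode]:
    return [n for n in root.iter_preorder() if pred(n)]
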