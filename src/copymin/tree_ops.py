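"""Gene-tree operations: low-support collapsing, outgroup rooting, MRCA.

Collapsing follows the convention that bipartition support is stored on
the child node of each internal edge: an internal edge is contracted
exactly when its child node carries a support strictly below the
threshold ("less than 50%" is a strict inequality — support exactly at
the threshold survives). Absent support is treated as fully supported
and is never collapsed.

Rooting places the root on the edge separating the outgroup leaves from
the rest; supports and branch lengths travel with their bipartitions, so
the unrooted topology is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._tree import GeneTree, TreeNode, mrca_node

__all__ = ["CollapseReport", "collapse_low_support", "root_by_outgroup", "mrca"]


@dataclass
class CollapseReport:
    """What a collapse pass removed."""

    threshold: float
    n_collapsed: int
    collapsed_supports: list = field(default_factory=list)


def collapse_low_support(
    tree: GeneTree, threshold: float = 50.0
) -> tuple[GeneTree, CollapseReport]:
    """Contract every internal edge whose child support is < ``threshold``.

    Children of a contracted node are promoted to its parent (producing a
    polytomy); the contracted edge's length, when present, is added to each
    promoted child so leaf-to-root path lengths are preserved. The input
    tree is not modified. A fully collapsed tree degenerates to a star,
    which is valid.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    out = tree.copy()
    removed: list[float] = []
    for node in list(out.iter_nodes("postorder")):
        if node is out.root or node.is_leaf:
            continue
        if node.support is not None and node.support < threshold:
            removed.append(node.support)
            parent = node.parent
            idx = parent.children.index(node)
            for child in node.children:
                child.parent = parent
                if node.length is not None and child.length is not None:
                    child.length += node.length
            parent.children[idx : idx + 1] = node.children
            node.children = []
            node.parent = None
    return out, CollapseReport(threshold, len(removed), removed)


def mrca(tree: GeneTree, leaves) -> TreeNode:
    """Lowest node whose leaf set contains all the given leaf labels."""
    return mrca_node(tree.root, set(leaves))


def _reroot_above(tree: GeneTree, child: TreeNode) -> None:
    """Re-root ``tree`` in place on the edge above ``child``.

    Supports and branch lengths are re-assigned so that every edge keeps
    the support of the bipartition it induces; the full length of the
    split edge stays on ``child``'s side. A former root left with a single
    child is suppressed.
    """
    if child.parent is None:
        raise ValueError("cannot re-root above the root")
    if child.parent is tree.root and len(tree.root.children) == 2:
        return  # already rooted on this edge

    path: list[TreeNode] = []
    node = child.parent
    while node is not None:
        path.append(node)
        node = node.parent

    old_sup = {id(x): x.support for x in path}
    old_len = {id(x): x.length for x in path}
    child_sup, child_len = child.support, child.length

    # detach the path edges, then re-attach them flipped
    path[0].remove_child(child)
    for lower, upper in zip(path, path[1:]):
        upper.remove_child(lower)
    for lower, upper in zip(path, path[1:]):
        lower.add_child(upper)
        # the flipped edge keeps the support/length stored on its old child
        upper.support = old_sup[id(lower)]
        upper.length = old_len[id(lower)]

    pivot = path[0]
    pivot.support = child_sup  # same bipartition as the root edge's other side
    pivot.length = 0.0 if child_len is not None else None

    new_root = TreeNode()
    new_root.add_child(child)
    new_root.add_child(pivot)

    # suppress the old root if it became unary
    old_root = path[-1]
    if len(old_root.children) == 1:
        only = old_root.children[0]
        parent = old_root.parent
        if only.length is not None and old_root.length is not None:
            only.length += old_root.length
        elif only.length is None:
            only.length = old_root.length
        idx = parent.children.index(old_root)
        old_root.remove_child(only)
        only.parent = parent
        parent.children[idx] = only

    tree.root = new_root


def root_by_outgroup(tree: GeneTree, outgroup_leaves) -> GeneTree:
    """Root on the edge separating the outgroup leaves from the ingroup.

    If the outgroup leaves do not form one side of any edge of the
    unrooted topology, the tree is rooted on the edge above the smallest
    clade containing all of them and ``meta["outgroup_clean"]`` is set to
    False (the "outgroup_not_clean" condition); otherwise it is True.
    The input tree is not modified.
    """
    og = set(outgroup_leaves)
    if not og:
        raise ValueError("outgroup leaf set is empty")
    out = tree.copy()
    all_leaves = out.leaf_labels()
    missing = og - all_leaves
    if missing:
        raise KeyError(f"outgroup leaves not in tree: {sorted(missing)}")
    if og == all_leaves:
        raise ValueError("outgroup cannot contain every leaf of the tree")

    clean_node = None
    for node in out.iter_nodes():
        if node is out.root:
            continue
        side = node.leaf_labels()
        if side == og or all_leaves - side == og:
            clean_node = node
            break
    if clean_node is not None:
        _reroot_above(out, clean_node)
        out.meta["outgroup_clean"] = True
        return out

    # outgroup not monophyletic on the unrooted topology: fix an ingroup
    # direction, then root above the smallest clade containing the outgroup
    ingroup_leaf = next(l for l in out.leaves() if l.label not in og)
    _reroot_above(out, ingroup_leaf)
    smallest = mrca_node(out.root, og)
    if smallest is not out.root:
        _reroot_above(out, smallest)
    out.meta["outgroup_clean"] = False
    return out
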