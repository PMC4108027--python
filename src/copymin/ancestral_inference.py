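"""Minimum ancestral copy-number inference from annotated gene trees.

The question: given a gene-family tree over species that fall on two
sides of a focal ancestral split — by default mosses (side A) versus
vascular plants (side B) — what is the minimum number of gene copies the
A/B common ancestor must have carried? Under duplication and loss, every
clade containing genes from both sides ("spanning clade") is evidence for
one ancestral copy, and disjoint spanning clades are evidence for
distinct copies.

Counting starts at the most recent common ancestor of all A and B leaves
and recurses:

    f(v) = sum of f(c) over the spanning children c of v
         + 1 if the leftover leaves (those under v's non-spanning
             children, algal outgroup leaves excluded) still contain at
             least one A leaf and one B leaf

In the default ("paper") mode the +1 leftover bonus applies at any node:
a collapsed polytomy whose unplaced leaves mix both sides is read as one
extra ancestral copy. In "strict" mode the bonus applies only at nodes
with no spanning children, which on fully resolved trees makes both
modes equal to the number of minimal spanning nodes (spanning nodes none
of whose children are spanning) — the topological minimum. Strict never
exceeds paper mode.

A family whose tree lacks A leaves or B leaves entirely has no defined
count and is reported as ND (not detected).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from ._tree import GeneTree, TreeNode, mrca_node
from .lineage_model import FocalSplit, LineageScheme, default_scheme, lineage_of

__all__ = [
    "CladeRecord",
    "AncestralCountResult",
    "is_spanning",
    "min_ancestral_copies",
    "clade_report",
    "infer_on_tree",
]


class InferenceError(ValueError):
    pass


def _side_counts(
    node: TreeNode, scheme: LineageScheme, split: FocalSplit
) -> tuple[int, int]:
    """(#A leaves, #B leaves) under ``node``; outgroup/other leaves ignored."""
    n_a = n_b = 0
    for leaf in node.leaves():
        side = split.side_of(leaf, scheme)
        if side == "A":
            n_a += 1
        elif side == "B":
            n_b += 1
    return n_a, n_b


def is_spanning(
    node: TreeNode, scheme: LineageScheme, split: Optional[FocalSplit] = None
) -> bool:
    """True iff the clade at ``node`` holds >= 1 A leaf and >= 1 B leaf."""
    split = split or FocalSplit()
    n_a, n_b = _side_counts(node, scheme, split)
    return n_a > 0 and n_b > 0


@dataclass
class CladeRecord:
    """One counted (or surfaced-but-uncounted) clade in a result."""

    node: TreeNode
    kind: str  # "spanning_clade" | "polytomy_bonus" | "uncounted"
    n_a: int
    n_b: int
    support: Optional[float]
    group_counts: Counter = field(default_factory=Counter)
    leaf_sample: list = field(default_factory=list)

    @property
    def counted(self) -> bool:
        return self.kind != "uncounted"


@dataclass
class AncestralCountResult:
    """Outcome of :func:`min_ancestral_copies` for one family."""

    family: Optional[str]
    mode: str
    min_copies: Optional[int]  # None exactly when nd is True
    nd: bool
    spanning_clades: list = field(default_factory=list)
    polytomy_bonus_nodes: list = field(default_factory=list)
    uncounted_clades: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nd:
            assert self.min_copies == len(self.spanning_clades) + len(
                self.polytomy_bonus_nodes
            )


def _record(
    node: TreeNode, kind: str, scheme: LineageScheme, split: FocalSplit
) -> CladeRecord:
    groups: Counter = Counter()
    n_a = n_b = 0
    leaves = node.leaves()
    for leaf in leaves:
        groups[lineage_of(leaf, scheme)] += 1
        side = split.side_of(leaf, scheme)
        if side == "A":
            n_a += 1
        elif side == "B":
            n_b += 1
    return CladeRecord(
        node=node,
        kind=kind,
        n_a=n_a,
        n_b=n_b,
        support=node.support,
        group_counts=groups,
        leaf_sample=[l.label for l in leaves[:3]],
    )


def min_ancestral_copies(
    tree: GeneTree,
    scheme: Optional[LineageScheme] = None,
    split: Optional[FocalSplit] = None,
    mode: str = "paper",
    family: Optional[str] = None,
) -> AncestralCountResult:
    """Minimum copy number at the focal ancestor implied by the tree.

    The tree is expected collapsed, rooted and taxon-annotated; supports
    play no further role here. ``mode`` is "paper" (polytomy leftover
    bonus at any node, the default) or "strict" (bonus only where no
    child is spanning).
    """
    if mode not in ("paper", "strict"):
        raise ValueError(f"mode must be 'paper' or 'strict', got {mode!r}")
    scheme = scheme or default_scheme()
    split = split or FocalSplit()
    if tree.root is None or not tree.leaves():
        raise InferenceError("empty tree")

    sided = {
        leaf.label: split.side_of(leaf, scheme) for leaf in tree.leaves()
    }
    a_leaves = {l for l, s in sided.items() if s == "A"}
    b_leaves = {l for l, s in sided.items() if s == "B"}
    if not a_leaves and not b_leaves:
        raise InferenceError("tree contains only outgroup / out-of-split leaves")
    result = AncestralCountResult(family=family, mode=mode, min_copies=None, nd=True)
    if not a_leaves or not b_leaves:
        return result  # ND: one side not detected at all

    v0 = mrca_node(tree.root, a_leaves | b_leaves)

    def recurse(v: TreeNode) -> int:
        spanning_children = []
        other_children = []
        for c in v.children:
            (spanning_children if is_spanning(c, scheme, split) else other_children).append(c)
        total = sum(recurse(c) for c in spanning_children)
        leftover_a = leftover_b = 0
        for c in other_children:
            n_a, n_b = _side_counts(c, scheme, split)
            leftover_a += n_a
            leftover_b += n_b
            if not c.is_leaf and (n_a or n_b):
                result.uncounted_clades.append(_record(c, "uncounted", scheme, split))
        bonus_mixed = leftover_a > 0 and leftover_b > 0
        if bonus_mixed and (mode == "paper" or not spanning_children):
            total += 1
            if spanning_children:
                result.polytomy_bonus_nodes.append(
                    _record(v, "polytomy_bonus", scheme, split)
                )
            else:
                result.spanning_clades.append(
                    _record(v, "spanning_clade", scheme, split)
                )
        return total

    count = recurse(v0)
    result.min_copies = count
    result.nd = False
    result.__post_init__()
    return result


def clade_report(result: AncestralCountResult) -> pd.DataFrame:
    """One row per counted clade / bonus node (plus surfaced uncounted
    clades), with per-lineage-group leaf counts and the clade's support.
    An ND family yields an empty table carrying an ``nd`` attribute."""
    records = (
        result.spanning_clades + result.polytomy_bonus_nodes + result.uncounted_clades
    )
    groups = sorted({g for r in records for g in r.group_counts})
    rows = []
    for rec in records:
        name = rec.node.label or "+".join(rec.leaf_sample)
        row = {
            "node": f"polytomy[{name}]" if rec.kind == "polytomy_bonus" else name,
            "kind": rec.kind,
            "counted": rec.counted,
            "support": rec.support,
            "n_a": rec.n_a,
            "n_b": rec.n_b,
        }
        for g in groups:
            row[f"n_{g}"] = rec.group_counts.get(g, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["family"] = result.family
    df.attrs["nd"] = result.nd
    return df


def infer_on_tree(
    tree: GeneTree,
    taxon_map=None,
    scheme: Optional[LineageScheme] = None,
    split: Optional[FocalSplit] = None,
    threshold: float = 50.0,
    mode: str = "paper",
    family: Optional[str] = None,
) -> AncestralCountResult:
    """Full single-tree pipeline: annotate, collapse, root, count.

    Outgroup leaves (species in the ``algal_outgroup`` lineage group) are
    detected from the annotated tree; when present the tree is rooted on
    the edge separating them, otherwise it is processed as read (with the
    rooting it was written with).
    """
    from .tree_io import TaxonMap, assign_taxa
    from .tree_ops import collapse_low_support, root_by_outgroup

    scheme = scheme or default_scheme()
    taxon_map = taxon_map or TaxonMap.default()
    work = assign_taxa(tree.copy(), taxon_map)
    work, _ = collapse_low_support(work, threshold)
    og = [
        l.label
        for l in work.leaves()
        if l.species in scheme and scheme.group_of(l.species) == "algal_outgroup"
    ]
    if og and set(og) != work.leaf_labels():
        work = root_by_outgroup(work, og)
    return min_ancestral_copies(work, scheme, split, mode=mode, family=family)
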