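"""Newick gene-tree I/O and leaf -> species annotation.

Bootstrap supports are stored as internal node labels, the dialect RAxML
writes. Numeric internal labels are parsed as supports; anything else is
kept as a node name. Files written on either the 0-1 or the 0-100 scale
are accepted: with ``support_scale="auto"`` a tree whose largest numeric
internal label is <= 1 is assumed to be on the proportion scale and is
rescaled to percent.

The :class:`TaxonMap` resolves gene identifiers to species codes with an
ordered first-match-wins rule list; each rule is a regular expression
matched at the start of the identifier, so a plain species prefix works
as-is.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import dendropy

from ._tree import GeneTree, TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "NewickFormatError",
    "SupportScaleError",
    "TaxonMapError",
    "TaxonRule",
    "TaxonMap",
    "read_gene_tree",
    "parse_gene_tree",
    "write_gene_tree",
    "format_gene_tree",
    "assign_taxa",
]

UNKNOWN_SPECIES = "unknown"


class NewickFormatError(ValueError):
    """Raised when a Newick source cannot be parsed; names the offset."""


class SupportScaleError(ValueError):
    """Raised when a support value falls outside [0, 100] after scaling."""


class TaxonMapError(ValueError):
    """Raised for unmatched gene identifiers in strict mode."""


# --------------------------------------------------------------------------
# Newick reading / writing
# --------------------------------------------------------------------------

def _dendropy_to_gene_tree(dtree: dendropy.Tree) -> TreeNode:
    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(label=label, length=dnode.edge.length)
        node = TreeNode(length=dnode.edge.length)
        raw = dnode.label
        if raw is not None:
            try:
                node.support = float(raw)
            except ValueError:
                node.label = raw
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(dtree.seed_node)


def parse_gene_tree(newick: str, support_scale: str = "auto") -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Parameters
    ----------
    newick : str
        Newick source, supports as internal node labels.
    support_scale : {"auto", "percent", "proportion"}
        "percent" takes labels as-is; "proportion" multiplies by 100;
        "auto" multiplies by 100 only when every numeric internal label
        is <= 1.
    """
    if support_scale not in ("auto", "percent", "proportion"):
        raise ValueError(f"unknown support_scale: {support_scale!r}")
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        offset = (col - 1) if col else len(newick)
        raise NewickFormatError(
            f"unparseable Newick at byte offset {offset}"
            + (f" (line {line}, column {col})" if col else "")
            + f": {exc}"
        ) from exc
    root = _dendropy_to_gene_tree(dtree)
    tree = GeneTree(root)

    supports = [n.support for n in tree.iter_nodes() if n.support is not None]
    scale = support_scale
    if scale == "auto":
        scale = "proportion" if supports and max(supports) <= 1.0 else "percent"
    if scale == "proportion":
        for node in tree.iter_nodes():
            if node.support is not None:
                node.support *= 100.0
    for node in tree.iter_nodes():
        if node.support is not None and not (0.0 <= node.support <= 100.0):
            raise SupportScaleError(
                f"support {node.support} outside [0, 100] after scaling "
                f"(support_scale={support_scale!r})"
            )
    tree.validate()
    return tree


def read_gene_tree(path: Union[str, Path], support_scale: str = "auto") -> GeneTree:
    """Read a Newick gene tree file. See :func:`parse_gene_tree`."""
    text = Path(path).read_text(encoding="utf-8")
    return parse_gene_tree(text, support_scale=support_scale)


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def _gene_tree_to_dendropy(tree: GeneTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: TreeNode, dnode) -> None:
        if node.is_leaf:
            dnode.taxon = taxa.new_taxon(node.label)
        else:
            if node.support is not None:
                dnode.label = _format_number(node.support)
            elif node.label is not None:
                dnode.label = node.label
        dnode.edge.length = node.length
        for child in node.children:
            convert(child, dnode.new_child())

    convert(tree.root, dtree.seed_node)
    return dtree


def format_gene_tree(tree: GeneTree) -> str:
    """Serialise to a one-line Newick string (supports on the 0-100 scale)."""
    dtree = _gene_tree_to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=all(
            n.length is None for n in tree.iter_nodes()
        ),
    )
    return text.strip() + "\n"


def write_gene_tree(tree: GeneTree, path: Union[str, Path]) -> Path:
    """Write a gene tree as Newick; round-trips topology, labels, supports."""
    path = Path(path)
    path.write_text(format_gene_tree(tree), encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Taxon mapping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRule:
    """One ordered rule: regex ``pattern`` anchored at the identifier start."""

    pattern: str
    species: str

    def matches(self, gene_id: str) -> bool:
        return re.match(self.pattern, gene_id) is not None


class TaxonMap:
    """Ordered first-match-wins rules mapping gene identifiers to species."""

    def __init__(self, rules: Iterable[TaxonRule]):
        self.rules: list[TaxonRule] = list(rules)
        if not self.rules:
            raise TaxonMapError("taxon map must contain at least one rule")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "TaxonMap":
        return cls(TaxonRule(p, s) for p, s in pairs)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "TaxonMap":
        """Load a two-column TSV (pattern, species); '#' lines are comments."""
        rules = []
        for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TaxonMapError(f"{path}:{i}: expected 2 tab-separated columns")
            rules.append(TaxonRule(parts[0], parts[1]))
        return cls(rules)

    @classmethod
    def default(cls) -> "TaxonMap":
        """Map identifiers of the form ``<species>_...`` (the convention used
        by the packaged fixtures and the simulator) to their species code."""
        from .lineage_model import default_scheme

        return cls.from_pairs(
            [(sp, sp) for sp in sorted(default_scheme().groups)]
        )

    def resolve(self, gene_id: str) -> Optional[str]:
        for rule in self.rules:
            if rule.matches(gene_id):
                return rule.species
        return None

    def species_codes(self) -> set[str]:
        return {r.species for r in self.rules}

    def __len__(self) -> int:
        return len(self.rules)


def assign_taxa(tree: GeneTree, taxon_map: TaxonMap, strict: bool = True) -> GeneTree:
    """Annotate every leaf with a species code (in place; returns the tree).

    In strict mode an unmatched leaf raises :class:`TaxonMapError` listing
    the offending labels; otherwise unmatched leaves get the designated
    ``"unknown"`` code and are reported via a logged warning.
    """
    unmatched = []
    for leaf in tree.leaves():
        species = taxon_map.resolve(leaf.label)
        if species is None:
            unmatched.append(leaf.label)
            leaf.species = UNKNOWN_SPECIES
        else:
            leaf.species = species
    if unmatched:
        if strict:
            raise TaxonMapError(
                f"no taxon-map rule matches leaves: {sorted(unmatched)}"
            )
        log.warning(
            "%d leaves unmatched by taxon map, assigned %r: %s",
            len(unmatched), UNKNOWN_SPECIES, sorted(unmatched),
        )
    return tree
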