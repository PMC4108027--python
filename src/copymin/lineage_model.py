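"""Species -> lineage-group assignments and the focal ancestral split.

The default scheme covers the ten sequenced plant genomes of the study
system — seven angiosperms (five eudicots, two monocots), the lycophyte
*Selaginella moellendorffii*, the moss *Physcomitrella patens* and the
chlorophyte *Chlamydomonas reinhardtii* — plus the three charophyte algae
(*Nitella hyalina*, *Penium margaritaceum*, *Spirogyra pratensis*) used
as additional outgroups. The default focal split asks how many gene
copies the common ancestor of mosses (side A) and vascular plants
(side B: lycophytes + monocots + eudicots) must have carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from ._tree import TreeNode

__all__ = [
    "LINEAGE_GROUPS",
    "SchemeError",
    "LineageScheme",
    "FocalSplit",
    "default_scheme",
    "load_scheme",
    "lineage_of",
    "DEFAULT_SPECIES_TREE",
]

LINEAGE_GROUPS = frozenset(
    {
        "bryophyte",
        "lycophyte",
        "monocot",
        "eudicot",
        "basal_angiosperm",
        "algal_outgroup",
        "other",
    }
)


class SchemeError(ValueError):
    """Raised for unknown species or lineage groups."""


_DEFAULT_GROUPS = {
    "physcomitrella": "bryophyte",
    "selaginella": "lycophyte",
    "oryza": "monocot",
    "sorghum": "monocot",
    "arabidopsis": "eudicot",
    "carica": "eudicot",
    "populus": "eudicot",
    "medicago": "eudicot",
    "vitis": "eudicot",
    "chlamydomonas": "algal_outgroup",
    "nitella": "algal_outgroup",
    "penium": "algal_outgroup",
    "spirogyra": "algal_outgroup",
    "unknown": "other",
}

#: Rooted species tree over the ten genome species, unit branch lengths.
#: Internal node names label the ancestors the simulator reports truth at;
#: ``land_plants`` is the moss/tracheophyte split ancestor.
DEFAULT_SPECIES_TREE = (
    "(chlamydomonas:1.0,(physcomitrella:1.0,(selaginella:1.0,"
    "((oryza:1.0,sorghum:1.0)monocots:1.0,"
    "(vitis:1.0,((carica:1.0,arabidopsis:1.0)brassicales:1.0,"
    "(populus:1.0,medicago:1.0)fabids:1.0)rosids:1.0)eudicots:1.0)"
    "angiosperms:1.0)tracheophytes:1.0)land_plants:1.0)root;"
)


@dataclass
class LineageScheme:
    """Mapping species code -> lineage group, with a species-tree reference."""

    groups: dict[str, str]
    species_tree: Optional[str] = None

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in LINEAGE_GROUPS}
        if bad:
            raise SchemeError(
                f"unknown lineage groups {sorted(bad)}; "
                f"allowed: {sorted(LINEAGE_GROUPS)}"
            )

    def group_of(self, species: str) -> str:
        try:
            return self.groups[species]
        except KeyError:
            raise SchemeError(f"species {species!r} not in lineage scheme") from None

    def species_in(self, lineage_groups: Iterable[str]) -> set[str]:
        wanted = set(lineage_groups)
        return {sp for sp, g in self.groups.items() if g in wanted}

    def __contains__(self, species: str) -> bool:
        return species in self.groups


def default_scheme() -> LineageScheme:
    return LineageScheme(dict(_DEFAULT_GROUPS), species_tree=DEFAULT_SPECIES_TREE)


def load_scheme(path: Union[str, Path]) -> LineageScheme:
    """Load a TSV of (species, group) rows; '#' lines are comments."""
    groups: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemeError(f"{path}:{i}: expected 2 tab-separated columns")
        species, group = parts
        if group not in LINEAGE_GROUPS:
            raise SchemeError(f"{path}:{i}: unknown lineage group {group!r}")
        groups[species] = group
    return LineageScheme(groups)


def lineage_of(leaf_or_species: Union[TreeNode, str], scheme: LineageScheme) -> str:
    """Lineage group of an annotated leaf (or a bare species code)."""
    if isinstance(leaf_or_species, TreeNode):
        species = leaf_or_species.species
        if species is None:
            raise SchemeError(
                f"leaf {leaf_or_species.label!r} has no species annotation; "
                "run assign_taxa first"
            )
    else:
        species = leaf_or_species
    return scheme.group_of(species)


@dataclass(frozen=True)
class FocalSplit:
    """The two disjoint lineage sides whose common ancestor is interrogated.

    Members of ``set_a`` / ``set_b`` may be lineage-group names or explicit
    species codes. Algal outgroup taxa can never belong to either side.
    """

    set_a: frozenset = field(default_factory=lambda: frozenset({"bryophyte"}))
    set_b: frozenset = field(
        default_factory=lambda: frozenset({"lycophyte", "monocot", "eudicot"})
    )

    def __post_init__(self) -> None:
        a, b = frozenset(self.set_a), frozenset(self.set_b)
        object.__setattr__(self, "set_a", a)
        object.__setattr__(self, "set_b", b)
        if not a or not b:
            raise ValueError("both sides of the focal split must be non-empty")
        if a & b:
            raise ValueError(f"focal split sides overlap: {sorted(a & b)}")
        if "algal_outgroup" in a | b:
            raise ValueError("algal_outgroup taxa cannot be a focal-split side")

    def side_of(
        self, leaf_or_species: Union[TreeNode, str], scheme: LineageScheme
    ) -> Optional[str]:
        """Return "A", "B", or None (outgroup / outside the split)."""
        species = (
            leaf_or_species.species
            if isinstance(leaf_or_species, TreeNode)
            else leaf_or_species
        )
        if species is None:
            raise SchemeError("leaf has no species annotation; run assign_taxa first")
        group = scheme.group_of(species)
        if group == "algal_outgroup":
            return None
        if species in self.set_a or group in self.set_a:
            return "A"
        if species in self.set_b or group in self.set_b:
            return "B"
        return None
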