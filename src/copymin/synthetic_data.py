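"""Duplication-loss gene-family simulation and packaged figure fixtures.

The simulator evolves ``k0`` ancestral gene copies down a rooted species
tree under a linear birth-death model: along a branch of length ``t``
each extant copy duplicates at rate ``lambda`` (both daughters continue
along the same branch) and is lost at rate ``mu``; copies reaching a
speciation node are inherited by every child branch. Copies extinct
everywhere are pruned, and a truth table records — for every species-tree
node — the number of copies entering that node that leave at least one
surviving descendant: the quantity a topology-based method could at best
recover. The bryophyte/tracheophyte split ancestor (``land_plants`` in
the default species tree) is the node the inference is benchmarked at.

Bootstrap supports are assigned synthetically rather than by resampling:
``degrade_supports`` gives an exact fraction ``p`` of internal edges a
support drawn uniformly below the collapse threshold and all others 100,
reproducing the unresolved-polytomy regime of real genome-scale trees
after collapsing.

``make_figure_fixtures`` builds the 17 small Newick trees whose clade
compositions mirror the published family-tree descriptions (GAUT, PG,
PME, HG methyltransferase, pectate lyase-like, the seven single-ancestor
families, the four families with no moss members, and the GAUT
superfamily); these are the packaged test and acceptance inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ._tree import GeneTree, TreeNode
from .lineage_model import DEFAULT_SPECIES_TREE
from .tree_io import parse_gene_tree, write_gene_tree

__all__ = [
    "SimulationConfig",
    "GeneFamilyEvent",
    "SimulatedFamily",
    "simulate_family",
    "degrade_supports",
    "make_figure_fixtures",
    "FIXTURE_FAMILIES",
]

SPLIT_NODE = "land_plants"


@dataclass
class SimulationConfig:
    """Parameters of one simulated gene family.

    Rates are events per copy per unit branch length. ``p_weak`` is the
    fraction of internal edges whose support is drawn below ``threshold``
    (the rest get 100).
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    k0: int = 1
    dup_rate: float = 0.3
    loss_rate: float = 0.2
    p_weak: float = 0.0
    threshold: float = 50.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be a positive integer")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.p_weak <= 1.0):
            raise ValueError("p_weak must lie in [0, 1]")


@dataclass
class GeneFamilyEvent:
    kind: str  # "duplication" | "loss"
    branch: str  # species-tree node the branch leads to
    time: float  # position along that branch, from its top
    copy_id: int


@dataclass
class SimulatedFamily:
    """A simulated gene tree with its ground truth.

    ``truth`` maps species-tree node name -> copies entering that node
    with >= 1 surviving descendant; ``truth_at_split`` is the count at the
    moss/tracheophyte ancestor. ``tree`` is None when every copy went
    extinct (``extinct`` flags this).
    """

    tree: Optional[GeneTree]
    truth: dict[str, int]
    events: list[GeneFamilyEvent] = field(default_factory=list)
    extinct: bool = False
    config: Optional[SimulationConfig] = None

    @property
    def truth_at_split(self) -> int:
        return self.truth.get(SPLIT_NODE, 0)


def _species_node_name(snode: TreeNode, index: int) -> str:
    if snode.is_leaf:
        return snode.label
    return snode.label or f"node{index}"


def simulate_family(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedFamily:
    """Simulate one gene family; deterministic for a fixed seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stree = (
        config.species_tree
        if isinstance(config.species_tree, GeneTree)
        else parse_gene_tree(config.species_tree)
    )
    names: dict[int, str] = {}
    for i, snode in enumerate(stree.iter_nodes()):
        names[id(snode)] = _species_node_name(snode, i)

    lam, mu = config.dup_rate, config.loss_rate
    total_rate = lam + mu
    truth: dict[str, int] = {names[id(n)]: 0 for n in stree.iter_nodes()}
    events: list[GeneFamilyEvent] = []
    leaf_counters: dict[str, int] = {}
    copy_counter = [0]

    def new_copy_id() -> int:
        copy_counter[0] += 1
        return copy_counter[0]

    def at_node(snode: TreeNode, copy_id: int) -> Optional[TreeNode]:
        """Copy arriving at species node ``snode``; returns surviving subtree."""
        if snode.is_leaf:
            sp = snode.label
            leaf_counters[sp] = leaf_counters.get(sp, 0) + 1
            gnode = TreeNode(label=f"{sp}_{leaf_counters[sp]}", species=sp, length=0.0)
            truth[names[id(snode)]] += 1
            return gnode
        subs = []
        for child in snode.children:
            sub = along_branch(child, child.length or 0.0, 0.0, copy_id)
            if sub is not None:
                subs.append(sub)
        if not subs:
            return None
        truth[names[id(snode)]] += 1
        if len(subs) == 1:
            return subs[0]  # speciation node with one surviving side: suppress
        gnode = TreeNode(length=0.0)
        for sub in subs:
            gnode.add_child(sub)
        return gnode

    def along_branch(
        starget: TreeNode, remaining: float, elapsed: float, copy_id: int
    ) -> Optional[TreeNode]:
        """Copy lineage descending the branch into ``starget``."""
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if wait >= remaining:
                sub = at_node(starget, copy_id)
                if sub is not None:
                    sub.length = (sub.length or 0.0) + remaining
                return sub
            elapsed += wait
            remaining -= wait
            if rng.random() < (lam / total_rate if total_rate else 0.0):
                left_id, right_id = copy_id, new_copy_id()
                events.append(
                    GeneFamilyEvent(
                        "duplication", names[id(starget)], elapsed, copy_id
                    )
                )
                left = along_branch(starget, remaining, elapsed, left_id)
                right = along_branch(starget, remaining, elapsed, right_id)
                if left is not None and right is not None:
                    gnode = TreeNode(length=0.0)
                    gnode.add_child(left)
                    gnode.add_child(right)
                    return gnode
                return left if left is not None else right
            events.append(
                GeneFamilyEvent("loss", names[id(starget)], elapsed, copy_id)
            )
            return None

    roots = []
    for _ in range(config.k0):
        sub = at_node(stree.root, new_copy_id())
        if sub is not None:
            roots.append(sub)

    if not roots:
        return SimulatedFamily(
            tree=None, truth=truth, events=events, extinct=True, config=config
        )
    if len(roots) == 1:
        groot = roots[0]
        groot.parent = None
    else:
        groot = TreeNode()
        for sub in roots:
            groot.add_child(sub)
    tree = GeneTree(groot)
    for node in tree.internal_nodes(include_root=False):
        node.support = 100.0
    family = SimulatedFamily(
        tree=tree, truth=truth, events=events, extinct=False, config=config
    )
    if config.p_weak > 0:
        family = degrade_supports(
            family, config.p_weak, rng=rng, threshold=config.threshold
        )
    return family


def degrade_supports(
    family: SimulatedFamily,
    p: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    threshold: float = 50.0,
) -> SimulatedFamily:
    """Assign weak supports to an exact fraction ``p`` of internal edges.

    Exactly ``round(p * n_internal_edges)`` distinct internal edges get a
    support drawn uniformly in [0, threshold); all others get 100. Returns
    a new SimulatedFamily; the input is untouched.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if family.tree is None:
        return family
    rng = rng if rng is not None else np.random.default_rng(seed)
    tree = family.tree.copy()
    internal = tree.internal_nodes(include_root=False)
    n_weak = int(round(p * len(internal)))
    weak_idx = set(
        rng.choice(len(internal), size=n_weak, replace=False)
    ) if internal else set()
    for i, node in enumerate(internal):
        if i in weak_idx:
            node.support = float(rng.uniform(0.0, threshold))
        else:
            node.support = 100.0
    return SimulatedFamily(
        tree=tree,
        truth=dict(family.truth),
        events=list(family.events),
        extinct=family.extinct,
        config=family.config,
    )


# --------------------------------------------------------------------------
# Figure fixtures
# --------------------------------------------------------------------------

FIXTURE_FAMILIES = (
    "gaut",
    "polygalacturonase",
    "pectin_methylesterase",
    "hg_methyltransferase",
    "pectate_lyase_like",
    "udp_glca_epimerase",
    "udp_rhamnose_synthase",
    "pectin_acetylesterase",
    "pectin_acetyltransferase",
    "rgii_xylosyltransferase",
    "galactan_galactosyltransferase",
    "gatl",
    "xga_xylosyltransferase",
    "rgi_arabinosyltransferase",
    "pmei",
    "pgip",
    "gaut_superfamily",
)


class _LeafFactory:
    """Unique ``<species>_<n>`` labels within one fixture tree."""

    def __init__(self) -> None:
        self.counters: dict[str, int] = {}

    def leaf(self, species: str) -> TreeNode:
        self.counters[species] = self.counters.get(species, 0) + 1
        return TreeNode(label=f"{species}_{self.counters[species]}", species=species)


def _clade(lf: _LeafFactory, species_list, support: Optional[float] = 100.0) -> TreeNode:
    node = TreeNode(support=support)
    for sp in species_list:
        node.add_child(lf.leaf(sp))
    return node


def _node(children, support: Optional[float] = 100.0) -> TreeNode:
    node = TreeNode(support=support)
    for c in children:
        node.add_child(c)
    return node


_SPANNING = ("physcomitrella", "physcomitrella", "selaginella", "oryza", "arabidopsis")
_NO_MOSS = ("selaginella", "oryza", "sorghum", "arabidopsis", "vitis")
_TRACHEOPHYTES = ("selaginella", "oryza", "arabidopsis", "populus", "vitis")


def _moss_sister_fixture(lf: _LeafFactory, n_moss: int, alga: Optional[str]) -> GeneTree:
    """All moss genes in one clade sister to all tracheophyte genes."""
    land = _node(
        [
            _clade(lf, ["physcomitrella"] * n_moss, 100.0)
            if n_moss > 1
            else lf.leaf("physcomitrella"),
            _clade(lf, _TRACHEOPHYTES, 100.0),
        ],
        support=100.0,
    )
    if alga is None:
        land.support = None
        return GeneTree(land)
    root = TreeNode()
    root.add_child(lf.leaf(alga))
    root.add_child(land)
    return GeneTree(root)


def _build_fixture(name: str) -> GeneTree:
    lf = _LeafFactory()
    if name == "gaut":
        # two resolved spanning clades, one moss-free clade, loose moss and
        # angiosperm leaves (two of them held by a weak node that collapses
        # away), and the algal leaf, all in the root polytomy
        root = TreeNode()
        root.add_child(lf.leaf("spirogyra"))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _NO_MOSS))
        weak = _node([lf.leaf("physcomitrella"), lf.leaf("arabidopsis")], support=30.0)
        root.add_child(weak)
        root.add_child(lf.leaf("oryza"))
        return GeneTree(root)
    if name == "polygalacturonase":
        # four spanning clades plus loose moss and lycophyte leaves in a
        # root polytomy with the chlorophyte algal leaf
        root = TreeNode()
        root.add_child(lf.leaf("chlamydomonas"))
        for _ in range(4):
            root.add_child(_clade(lf, _SPANNING))
        weak = _node([lf.leaf("physcomitrella"), lf.leaf("selaginella")], support=42.0)
        root.add_child(weak)
        root.add_child(lf.leaf("physcomitrella"))
        root.add_child(lf.leaf("selaginella"))
        return GeneTree(root)
    if name == "pectin_methylesterase":
        # two spanning clades in the root polytomy (with the algal leaf and
        # loose moss/tracheophyte leaves), a third resolved spanning clade,
        # and a moss+lycophyte subclade sister to an angiosperm-only polytomy
        root = TreeNode()
        root.add_child(lf.leaf("penium"))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _SPANNING))
        blue = _node(
            [
                _clade(lf, ["physcomitrella", "physcomitrella", "selaginella"]),
                _clade(lf, ["oryza", "sorghum", "arabidopsis", "vitis", "medicago"]),
            ],
            support=100.0,
        )
        root.add_child(blue)
        root.add_child(lf.leaf("physcomitrella"))
        root.add_child(lf.leaf("oryza"))
        root.add_child(lf.leaf("vitis"))
        return GeneTree(root)
    if name == "hg_methyltransferase":
        # no algal root detected; two spanning clades and one angiosperm-only
        root = TreeNode()
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, ["oryza", "arabidopsis", "populus"]))
        return GeneTree(root)
    if name == "pectate_lyase_like":
        # one small spanning clade resolved from the rest of the tree,
        # which also mixes moss and tracheophyte leaves
        rest = _node(
            [
                lf.leaf("physcomitrella"),
                lf.leaf("physcomitrella"),
                lf.leaf("selaginella"),
                lf.leaf("oryza"),
                lf.leaf("arabidopsis"),
                lf.leaf("vitis"),
            ],
            support=100.0,
        )
        root = TreeNode()
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(rest)
        return GeneTree(root)
    if name == "udp_glca_epimerase":
        return _moss_sister_fixture(lf, n_moss=4, alga="chlamydomonas")
    if name == "udp_rhamnose_synthase":
        # land-plant-wide with three algal genes outside
        lf2 = _LeafFactory()
        land = _node(
            [
                _clade(lf2, ["physcomitrella"] * 3, 100.0),
                _clade(lf2, _TRACHEOPHYTES, 100.0),
            ],
            support=100.0,
        )
        root = TreeNode()
        root.add_child(lf2.leaf("chlamydomonas"))
        root.add_child(lf2.leaf("spirogyra"))
        root.add_child(lf2.leaf("penium"))
        root.add_child(land)
        return GeneTree(root)
    if name == "pectin_acetylesterase":
        return _moss_sister_fixture(lf, n_moss=1, alga="chlamydomonas")
    if name == "pectin_acetyltransferase":
        return _moss_sister_fixture(lf, n_moss=3, alga="chlamydomonas")
    if name == "rgii_xylosyltransferase":
        return _moss_sister_fixture(lf, n_moss=1, alga="nitella")
    if name == "galactan_galactosyltransferase":
        return _moss_sister_fixture(lf, n_moss=4, alga=None)
    if name == "gatl":
        return _moss_sister_fixture(lf, n_moss=3, alga=None)
    if name == "xga_xylosyltransferase":
        return GeneTree(_node([lf.leaf("arabidopsis"), lf.leaf("arabidopsis")], None))
    if name == "rgi_arabinosyltransferase":
        return GeneTree(
            _node(
                [lf.leaf("arabidopsis"), lf.leaf("arabidopsis"), lf.leaf("oryza")],
                None,
            )
        )
    if name == "pmei":
        return GeneTree(
            _node(
                [lf.leaf("arabidopsis"), lf.leaf("arabidopsis"), lf.leaf("medicago")],
                None,
            )
        )
    if name == "pgip":
        return GeneTree(
            _node(
                [lf.leaf("arabidopsis"), lf.leaf("arabidopsis"), lf.leaf("vitis")],
                None,
            )
        )
    if name == "gaut_superfamily":
        # the GAUT composition plus the GATL clade as one more land-plant-
        # wide clade derived from within the family
        root = TreeNode()
        root.add_child(lf.leaf("spirogyra"))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _SPANNING))
        root.add_child(_clade(lf, _NO_MOSS))
        root.add_child(_clade(lf, _SPANNING))  # GATL clade
        root.add_child(lf.leaf("physcomitrella"))
        root.add_child(lf.leaf("oryza"))
        return GeneTree(root)
    raise KeyError(f"unknown fixture family {name!r}")


def make_figure_fixtures(
    out_dir: Optional[Union[str, Path]] = None
) -> dict[str, GeneTree]:
    """Build (and optionally write) the packaged family fixture trees.

    Content is deterministic. When ``out_dir`` is given, each tree is
    written there as ``<family>.tree``.
    """
    fixtures = {name: _build_fixture(name) for name in FIXTURE_FAMILIES}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, tree in fixtures.items():
            write_gene_tree(tree, out_dir / f"{name}.tree")
    return fixtures
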