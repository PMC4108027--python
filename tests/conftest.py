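import random

import pytest

from copymin import (
    FocalSplit,
    GeneTree,
    TaxonMap,
    TreeNode,
    default_scheme,
    make_figure_fixtures,
)

SPECIES_POOL = [
    "physcomitrella",
    "selaginella",
    "oryza",
    "sorghum",
    "arabidopsis",
    "vitis",
    "medicago",
    "populus",
    "carica",
    "chlamydomonas",
]


def random_binary_tree(
    rng: random.Random,
    n_leaves: int,
    species_pool=SPECIES_POOL,
    with_supports: bool = False,
) -> GeneTree:
    """Random rooted binary tree; leaves get random species annotations."""
    nodes = []
    for i in range(n_leaves):
        sp = rng.choice(species_pool)
        nodes.append(TreeNode(label=f"{sp}_{i}", species=sp))
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = TreeNode(
            support=float(rng.randint(0, 100)) if with_supports else None
        )
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.support = None
    return GeneTree(root)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def split():
    return FocalSplit()


@pytest.fixture(scope="session")
def taxon_map():
    return TaxonMap.default()


@pytest.fixture(scope="session")
def figure_fixtures():
    return make_figure_fixtures()
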