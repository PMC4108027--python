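"""Duplication-loss simulator: determinism, truth bookkeeping, support
degradation, and agreement between simulated truth and the inference."""

import numpy as np
import pytest

from copymin import (
    SimulationConfig,
    collapse_low_support,
    degrade_supports,
    format_gene_tree,
    infer_on_tree,
    make_figure_fixtures,
    simulate_family,
)
from copymin.ancestral_inference import InferenceError
from copymin.synthetic_data import FIXTURE_FAMILIES


def inferred_count(tree, mode="paper"):
    try:
        res = infer_on_tree(tree, mode=mode)
    except InferenceError:
        return 0
    return 0 if res.nd else res.min_copies


class TestSimulateFamily:
    def test_no_events_single_copy_tracks_species_tree(self):
        fam = simulate_family(SimulationConfig(k0=1, dup_rate=0, loss_rate=0, seed=1))
        assert not fam.extinct
        assert all(v == 1 for v in fam.truth.values())
        # one gene leaf per species
        species = sorted(l.species for l in fam.tree.leaves())
        assert len(species) == 10 and len(set(species)) == 10

    def test_no_events_three_copies_forced_count(self):
        fam = simulate_family(SimulationConfig(k0=3, dup_rate=0, loss_rate=0, seed=1))
        assert fam.truth_at_split == 3
        assert len(fam.tree.root.children) == 3
        assert inferred_count(fam.tree) == 3

    def test_seed_determinism(self):
        a = simulate_family(SimulationConfig(k0=2, dup_rate=0.4, loss_rate=0.3, seed=9))
        b = simulate_family(SimulationConfig(k0=2, dup_rate=0.4, loss_rate=0.3, seed=9))
        assert a.truth == b.truth
        assert [(e.kind, e.branch, e.copy_id) for e in a.events] == [
            (e.kind, e.branch, e.copy_id) for e in b.events
        ]
        if a.tree is not None:
            assert format_gene_tree(a.tree) == format_gene_tree(b.tree)

    def test_all_extinct_is_flagged_not_an_error(self):
        # overwhelming loss: everything dies almost immediately
        fam = simulate_family(
            SimulationConfig(k0=1, dup_rate=0.0, loss_rate=200.0, seed=3)
        )
        assert fam.extinct and fam.tree is None
        assert fam.truth_at_split == 0

    def test_leaf_count_equals_truth_at_species_tips(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            fam = simulate_family(
                SimulationConfig(k0=2, dup_rate=0.3, loss_rate=0.2), rng=rng
            )
            if fam.tree is None:
                continue
            per_species = {}
            for leaf in fam.tree.leaves():
                per_species[leaf.species] = per_species.get(leaf.species, 0) + 1
            for sp, n in per_species.items():
                assert fam.truth[sp] == n

    def test_truth_conserved_through_speciation_nodes(self):
        # a lineage surviving a node must have survived the branch into it:
        # entering copies at a node can never exceed those at its parent
        # times at most (1 + duplications on the branch)
        rng = np.random.default_rng(12)
        for _ in range(20):
            fam = simulate_family(
                SimulationConfig(k0=2, dup_rate=0.5, loss_rate=0.3), rng=rng
            )
            dups_into = {}
            for ev in fam.events:
                if ev.kind == "duplication":
                    dups_into[ev.branch] = dups_into.get(ev.branch, 0) + 1
            parent_of = {
                "land_plants": "root", "chlamydomonas": "root",
                "physcomitrella": "land_plants", "tracheophytes": "land_plants",
                "selaginella": "tracheophytes", "angiosperms": "tracheophytes",
                "monocots": "angiosperms", "eudicots": "angiosperms",
            }
            for node, parent in parent_of.items():
                assert fam.truth[node] <= fam.truth[parent] + dups_into.get(node, 0)


class TestDegradeSupports:
    def test_p_zero_keeps_everything_resolved(self):
        fam = simulate_family(SimulationConfig(k0=2, dup_rate=0.5, loss_rate=0, seed=4))
        deg = degrade_supports(fam, 0.0, seed=1)
        collapsed, report = collapse_low_support(deg.tree, 50)
        assert report.n_collapsed == 0
        assert format_gene_tree(collapsed) == format_gene_tree(deg.tree)

    def test_p_one_collapses_to_star(self):
        fam = simulate_family(SimulationConfig(k0=1, dup_rate=0.6, loss_rate=0, seed=5))
        deg = degrade_supports(fam, 1.0, seed=1)
        collapsed, _ = collapse_low_support(deg.tree, 50)
        assert all(c.is_leaf for c in collapsed.root.children)
        assert inferred_count(collapsed) in (0, 1)

    def test_exact_fraction_of_weak_edges(self):
        fam = simulate_family(SimulationConfig(k0=3, dup_rate=0.5, loss_rate=0, seed=6))
        n_internal = fam.tree.n_internal_edges()
        for p in (0.25, 0.5, 0.75):
            deg = degrade_supports(fam, p, seed=2)
            weak = sum(
                1
                for n in deg.tree.internal_nodes(include_root=False)
                if n.support < 50
            )
            assert weak == round(p * n_internal)

    def test_fixed_seed_reproducible_and_input_untouched(self):
        fam = simulate_family(SimulationConfig(k0=2, dup_rate=0.5, loss_rate=0, seed=7))
        before = format_gene_tree(fam.tree)
        d1 = degrade_supports(fam, 0.5, seed=3)
        d2 = degrade_supports(fam, 0.5, seed=3)
        assert format_gene_tree(d1.tree) == format_gene_tree(d2.tree)
        assert format_gene_tree(fam.tree) == before


class TestRecoveryProperties:
    def test_no_loss_recovery_is_exact(self):
        rng = np.random.default_rng(2024)
        for k0 in (1, 3, 5):
            for lam in (0.0, 0.3):
                for _ in range(25):
                    fam = simulate_family(
                        SimulationConfig(k0=k0, dup_rate=lam, loss_rate=0.0), rng=rng
                    )
                    assert inferred_count(fam.tree) == fam.truth_at_split

    def test_with_loss_inference_is_a_lower_bound(self):
        rng = np.random.default_rng(2025)
        for _ in range(100):
            fam = simulate_family(
                SimulationConfig(k0=2, dup_rate=0.3, loss_rate=0.2), rng=rng
            )
            if fam.tree is None:
                continue
            assert inferred_count(fam.tree) <= fam.truth_at_split

    def test_strict_mode_bounded_by_paper_mode_under_degradation(self):
        rng = np.random.default_rng(2026)
        for _ in range(50):
            fam = simulate_family(
                SimulationConfig(k0=2, dup_rate=0.4, loss_rate=0.2), rng=rng
            )
            if fam.tree is None:
                continue
            deg = degrade_supports(fam, 0.4, rng=rng)
            assert inferred_count(deg.tree, "strict") <= inferred_count(
                deg.tree, "paper"
            )


class TestFigureFixtures:
    def test_all_seventeen_families_built(self, figure_fixtures):
        assert set(figure_fixtures) == set(FIXTURE_FAMILIES)
        assert len(figure_fixtures) == 17

    def test_content_is_deterministic(self, figure_fixtures):
        again = make_figure_fixtures()
        for name, tree in figure_fixtures.items():
            assert format_gene_tree(again[name]) == format_gene_tree(tree)

    def test_written_files_parse_back(self, tmp_path):
        from copymin import read_gene_tree

        make_figure_fixtures(tmp_path)
        files = sorted(tmp_path.glob("*.tree"))
        assert len(files) == 17
        for path in files:
            tree = read_gene_tree(path)
            assert tree.leaves()

    def test_inference_invariant_to_within_clade_leaf_counts(self, scheme):
        # enlarging each described clade with more leaves of lineages it
        # already contains must not change the count
        from copymin import GeneTree, TreeNode, infer_on_tree

        def build(n_per_lineage):
            root = TreeNode()
            root.add_child(TreeNode(label="spirogyra_x", species="spirogyra"))
            for c in range(2):
                clade = TreeNode(support=100.0)
                for sp in ("physcomitrella", "selaginella", "oryza", "arabidopsis"):
                    for i in range(n_per_lineage):
                        clade.add_child(
                            TreeNode(label=f"{sp}_{c}_{i}", species=sp)
                        )
                root.add_child(clade)
            root.add_child(TreeNode(label="physcomitrella_loose", species="physcomitrella"))
            root.add_child(TreeNode(label="oryza_loose", species="oryza"))
            return GeneTree(root)

        counts = {
            n: infer_on_tree(build(n)).min_copies for n in (1, 2, 3, 5)
        }
        assert set(counts.values()) == {3}
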