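"""Collapse weak nodes and root a gene tree with its algal outgroup.

Builds the packaged GAUT-family fixture tree, contracts every internal
edge whose bootstrap support is below 50%, and roots the result on the
edge leading to the algal gene.
"""

from copymin import (
    collapse_low_support,
    format_gene_tree,
    make_figure_fixtures,
    root_by_outgroup,
)

tree = make_figure_fixtures()["gaut"]
print("as built:     ", format_gene_tree(tree), end="")

collapsed, report = collapse_low_support(tree, threshold=50.0)
print(
    f"collapsed {report.n_collapsed} edge(s) with supports "
    f"{report.collapsed_supports} < {report.threshold}"
)
print("after collapse:", format_gene_tree(collapsed), end="")

rooted = root_by_outgroup(collapsed, {"spirogyra_1"})
print("rooted        :", format_gene_tree(rooted), end="")
print("outgroup clean:", rooted.meta["outgroup_clean"])
# The weakly supported (30%) grouping of a moss and an angiosperm gene is
# gone: its two leaves now sit loose in the root polytomy, which is how
# unresolved placements are represented downstream.
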