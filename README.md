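# copymin

Minimum ancestral gene copy-number inference from gene-family trees.

When did a gene family diversify? For plant cell-wall genes — the pectin
synthesis, modification and degradation machinery in particular — the
interesting split is between the mosses (represented by *Physcomitrella
patens*) and the vascular plants (lycophytes, monocots, eudicots). A
gene-family tree built from modern genomes contains the answer in its
clade structure: any clade holding genes from **both** sides of that
split must descend from a single gene already present in their common
ancestor, and disjoint such clades imply distinct ancestral genes.

`copymin` implements that inference as a small, tested library:

- **tree_io / tree_ops** — Newick gene trees with RAxML-style bootstrap
  supports as internal node labels; collapsing of nodes with support
  < 50% into polytomies; outgroup rooting (algal genes) that preserves
  the unrooted topology; MRCA queries; gene-ID → species mapping.
- **lineage_model** — species → lineage-group assignments for the ten
  plant genomes plus three charophyte algal outgroups, and the focal
  split (default: bryophyte vs lycophyte+monocot+eudicot).
- **ancestral_inference** — the count itself. With A/B the two sides of
  the split and "spanning" meaning a clade with ≥ 1 leaf from each
  side, the minimum copy number at the A/B ancestor is

      f(v) = Σ f(c) over spanning children c of v
           + 1[leftover leaves at v mix A and B]

  evaluated from the MRCA of all A∪B leaves; algal leaves are
  transparent. On binary trees this equals the number of minimal
  spanning nodes (spanning nodes with no spanning child). Families with
  no A-side (or no B-side) members return **ND**.
- **census** — per-family × per-species gene-count tables with totals
  and a packaged 16-family pectin reference census.
- **synthetic_data** — a duplication–loss birth–death simulator along
  the species tree with known copy number at every ancestor, synthetic
  bootstrap-support degradation, and 17 deterministic fixture trees
  mirroring the published family-tree clade compositions.
- **cli** — `copymin collapse | root | infer | census | simulate |
  fixtures | report`.

## Worked example

```python
from copymin import infer_on_tree, clade_report, make_figure_fixtures

tree = make_figure_fixtures()["gaut"]   # galacturonosyltransferase family
res = infer_on_tree(tree, threshold=50.0, mode="paper", family="gaut")
print(res.min_copies)
print(clade_report(res).to_string(index=False))
```

prints

```
3
                                                     node           kind  counted  support  n_a  n_b  n_bryophyte  n_eudicot  n_lycophyte  n_monocot
          physcomitrella_1+physcomitrella_2+selaginella_1 spanning_clade     True    100.0    2    3            2          1            1          1
          physcomitrella_3+physcomitrella_4+selaginella_2 spanning_clade     True    100.0    2    3            2          1            1          1
polytomy[physcomitrella_1+physcomitrella_2+selaginella_1] polytomy_bonus     True      NaN    5   13            5          5            3          5
                          selaginella_3+oryza_3+sorghum_1      uncounted    False    100.0    0    5            0          2            1          2
```

Three ancestral GAUT genes: two resolved clades each containing moss and
tracheophyte genes, plus one more implied by the moss and angiosperm
genes left unresolved in the root polytomy. The fourth row is a
lycophyte+angiosperm clade with no moss members — surfaced for
inspection, but evidence at a later split, so not counted. The same
pipeline on the whole fixture set gives 5 ancestral polygalacturonases,
5 pectin methylesterases, 2 homogalacturonan methyltransferases, 2
pectate lyase-like genes, 1 for each of the seven single-ancestor
families, and ND for the four families with no moss members.

From the shell:

```sh
copymin fixtures --out trees/
copymin infer --tree trees/polygalacturonase.tree --out pg.json
copymin simulate --k0 2 --dup 0.3 --loss 0.2 --seed 1 --reps 100 --out sims/
```

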