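# Methods

## The question and the estimator

Given a gene-family tree over species that straddle an ancestral split —
by default the moss *Physcomitrella patens* (side A) versus the vascular
plants: the lycophyte *Selaginella moellendorffii* plus monocots and
eudicots (side B) — `copymin` asks how many copies of the gene the A/B
common ancestor must have carried. Under vertical descent with
duplication and loss, a clade whose leaves include at least one A gene
and one B gene (a *spanning clade*) must trace back to a single gene
present in the A/B ancestor, and disjoint spanning clades must trace
back to distinct ancestral genes. The count is therefore a parsimony
*minimum*: losses can hide ancestral copies, but never manufacture
spurious ones.

Counting starts at the most recent common ancestor v0 of all A and B
leaves in the (rooted, collapsed, taxon-annotated) tree and recurses:

    f(v) = Σ_{c ∈ spanning children of v} f(c)
         + [leftover leaves at v contain ≥1 A and ≥1 B]

where the leftover leaves are those under v's non-spanning children,
with algal outgroup leaves excluded throughout. The bracket is the
*polytomy bonus*: when a collapsed polytomy holds unplaced genes from
both sides beside its resolved clades, those leftovers are read as one
additional ancestral copy.

Two counting modes are provided:

- **paper** (default): the bonus applies at every node. This mirrors how
  mixed polytomies are conventionally read in the genome-scale family
  trees this package targets.
- **strict**: the bonus applies only at nodes with no spanning child.
  On fully resolved (binary) trees both modes coincide with the number
  of *minimal spanning nodes* (spanning nodes none of whose children
  span), which is the true topological minimum; on collapsed trees the
  paper-mode bonus can exceed that minimum when collapsing has hidden
  nesting, which is why strict mode exists. Strict never exceeds paper
  mode.

A family whose tree has no A leaves or no B leaves gets **ND** (not
detected): no copy number at that ancestor is defined. The spanning
criterion is deliberately *moss AND any tracheophyte*, not
"every lineage present": the weaker criterion is the one consistent
with the published per-family counts this package reproduces, and is
robust to lineage-specific losses inside a clade. Non-spanning resolved
clades encountered during the recursion (e.g. a lycophyte+angiosperm
clade with no moss members) are surfaced in the clade report as
`uncounted` rows but contribute nothing to the count — they are
evidence at a *later* split, not this one.

## Tree post-processing

**Collapsing.** Bipartition supports are stored on the child node of
each internal edge (the RAxML convention). `collapse_low_support`
contracts exactly the internal edges whose child support is *strictly*
below the threshold (default 50%; a support of exactly 50 survives),
promoting the children into the parent and producing polytomies. Absent
support — leaves, the root, nodes of already-collapsed trees — is
treated as fully supported. Collapsing is idempotent at a fixed
threshold and composes monotonically: collapsing at t1 then t2 ≥ t1
equals collapsing at t2 directly. Contracted-edge branch lengths are
added to the promoted children so path lengths are preserved.

**Rooting.** `root_by_outgroup` places the root on the edge separating
the outgroup leaves from the ingroup, re-attaching supports and branch
lengths to the bipartitions they describe so the unrooted topology is
unchanged. If no edge of the unrooted topology has the outgroup as one
side, the tree is rooted above the smallest clade containing all
outgroup leaves and flagged `outgroup_clean = False`; the flagging
convention (rather than an error) is this package's choice, since real
trees do place algal genes inside root polytomies. Families with no
algal homolog are processed as read, with a warning — their published
counts were reported the same way.

**Support scales.** Newick internal labels that parse as numbers are
supports; `support_scale="auto"` treats a file whose largest numeric
label is ≤ 1 as proportions and rescales to percent. The corner case of
a tree whose only support is exactly 1 is resolved in favour of the
proportion reading (→ 100); pass `support_scale="percent"` to override.

## Lineage scheme and species set

The default scheme covers the ten genome species of the study system —
Arabidopsis, Carica, Populus, Medicago, Vitis (eudicots), Oryza,
Sorghum (monocots), Selaginella (lycophyte), Physcomitrella
(bryophyte), Chlamydomonas (chlorophyte outgroup) — plus the three
charophyte algae Nitella, Penium and Spirogyra as additional outgroups.
The seven-angiosperm composition follows the gene-family classification
database the study system is built on. Algal-outgroup species are
transparent to the inference: excluded from both split sides and from
the leftover bonus test. The focal split is expressed over lineage
groups (or explicit species codes), so the same machinery answers e.g.
monocot-vs-eudicot questions by setting A={monocot}, B={eudicot}.

## The simulator

`simulate_family` evolves `k0` ancestral copies down a rooted species
tree (default: the ten-species topology above with unit branch lengths)
under a linear birth–death model: per copy, duplications at rate λ and
losses at rate μ per unit branch length, both daughters of a
duplication continuing on the same branch; a copy reaching a speciation
node is inherited by every child branch. Copies extinct everywhere are
pruned. The truth table records, for every species-tree node, the
number of entering copies with ≥ 1 surviving descendant — the
best-recoverable quantity, since a copy with no surviving descendants
is invisible to any topology-based method. Default rates (λ=0.3, μ=0.2
per copy per unit length) give gene families of realistic size (tens of
leaves) on the unit-branch-length tree with non-trivial loss.

Supports are assigned synthetically, not by bootstrap resampling (the
inference consumes only the values): `degrade_supports(p)` gives an
exact `round(p · n_internal_edges)` subset of internal edges a support
uniform in [0, threshold) and all others 100, reproducing the
unresolved-polytomy regime of real collapsed trees. What the simulator
does *not* emulate: alignment and phylogenetic-reconstruction error
(topological mistakes, not just resolution loss), rate variation across
branches, gene conversion or transfer. Passing recovery tests therefore
shows the estimator is correct *given* a correct (possibly unresolved)
tree, not that real trees are correct.

Validated properties (each enforced by the test suite, per replicate):
with μ=0 and full resolution the inferred count equals the truth at the
moss/tracheophyte split for any k0 and λ tried; with μ>0 the inferred
count never exceeds the truth; strict mode never exceeds paper mode,
resolved or degraded. A replicate surviving only in the algal outgroup
raises (the tree contains no split-relevant leaves); harnesses count it
as 0, consistent with the lower-bound reading.

## Fixtures and the census

`make_figure_fixtures` builds 17 small deterministic Newick trees whose
clade compositions transcribe the published family-tree descriptions
(two resolved spanning clades + mixed polytomy + moss-free clade for
GAUT; four spanning clades + loose moss/lycophyte leaves for the
polygalacturonases; and so on). Figure-legend narratives do not fix the
leaf counts inside each described clade; fixtures use 2–3 leaves per
lineage per clade, and a test verifies the inferred count is invariant
to those counts. A few fixtures include a deliberately weak (< 50)
grouping that the collapse step must remove to recover the described
polytomy.

The census module counts gene identifiers per (family, species) from
(family, gene_id) tables, attaches per-family inference results, and
summarises totals; ND entries are never summed as numbers (they
contribute 0, with the ND count footnoted). A packaged 16-family
reference census (Arabidopsis and Physcomitrella counts plus ancestral
copies) exercises this path end to end without any download.

## Numerical and degenerate-input choices

- "Less than 50%" is strict inequality throughout.
- A cherry of one A leaf and one B leaf counts 1.
- A fully collapsed star tree yields 0 (no A or B side present → ND
  treated as 0 by harnesses) or 1 (leftover mixing at the root).
- TaxonMap rules are ordered, first match wins; each rule is a regex
  anchored at the identifier start, so a plain prefix is a valid rule.
- Seeds: all simulator randomness flows through a single
  `numpy.random.Generator`; a fixed seed reproduces trees, truth tables
  and event logs byte-for-byte.

## Problem sizes

Default validation runs use 100 replicates per parameter combination
for the simulation properties, 1000 random ≤10-leaf binary trees for
the oracle-equivalence check, and 500 random trees for the collapse
properties — sizes at which every property is checked exhaustively per
replicate in seconds.

## Known limitations

- The count is a minimum, not an estimate: it has no variance and no
  model of reconstruction error; collapsing discards, never corrects,
  topology.
- Full duplication–loss reconciliation (LCA mapping, loss counting) and
  probabilistic gene-tree/species-tree models are out of scope; so is
  inferring loss on the moss side from lycophyte+angiosperm clades.
- Paper-mode counts on heavily collapsed trees can exceed the strict
  topological minimum; both numbers are reported for a reason.
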