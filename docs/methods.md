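# Methods

## The screen

The unit of analysis is a per-gene phylogeny containing one (or more)
leaves of a focal archaeon, annotated with a leaf → (species, genus,
phylum, domain) taxonomy. The screen asks whether the focal gene's
phylogenetic position is compatible with vertical inheritance or instead
places it among bacteria or eukaryotes, which — for an organism whose
niche neighbors are almost exclusively bacteria — is the expected
signature of inter-domain lateral acquisition.

### Rooting

Gene trees produced by distance pipelines are unrooted; the sister group
of the focal leaf is only defined on a rooted tree. By default trees are
midpoint rooted: the root is placed at the midpoint of the longest
leaf-to-leaf path, computed by locating the diameter path explicitly and
bisecting the edge that contains its midpoint (the resulting maximal
root-to-leaf depth equals half the tree diameter, which the tests verify
by exhaustive scan). Midpoint rooting assumes an approximate molecular
clock at the whole-tree scale; for trees rooted upstream the
`rooting="as-provided"` configuration skips it. Bootstrap supports are
attached to bipartitions, not nodes, so they survive re-rooting.

### Classification rules

With the tree rooted, the focal leaf's sister group is examined in a
fixed order: exclusively archaeal and not purely the companion genus →
`non_LGT`; exclusively bacterial → `LGT_bacterial_neighbor`; exclusively
companion-genus → the smallest clade holding the focal leaf plus those
companions is formed, and if *its* sister is a **bacterial clade** (all
bacteria, ≥ `min_bacterial_phyla` = 3 distinct phyla), the gene is an
`LGT_nested_methanogen_pair` — a transfer that preceded the divergence of
the focal and companion genera; exclusively eukaryotic →
`LGT_eukaryote_neighbor`; any mixed-domain sister → `non_LGT` with a
review note, since the screen's criteria name pure neighbor groups and a
mixed group is better triaged by eye than guessed at. The ≥ 3-phyla
requirement exists so that a single misannotated or contaminant bacterial
leaf cannot masquerade as a bacterial origin.

With several focal paralogs each is classified independently and the
per-gene verdict is LGT if any copy is LGT (per-leaf detail is kept).

### Direction of transfer

Direction is only claimed when the nesting is unambiguous. The rooted
tree's two basal branches are an artifact of rooting an unrooted tree, so
a focal clade whose bacterial enclosure sits directly opposite the rest
of the tree cannot be oriented — that pattern is exactly what a vertical
archaeal gene with a basal bacterial sister would produce under an
arbitrary root. Operationally, `bacteria_to_archaea` requires at least
two successive enclosing clades below the root whose added members are
all bacterial, jointly spanning ≥ 3 phyla; `eukarya_to_archaea` is the
analogue with eukaryotic enclosures. `archaea_to_bacteria` covers the
opposite event — a small bacterial insert (≤ 3 leaves by default) whose
enclosing clades are otherwise purely archaeal across ≥ 2 genera beyond
the focal genus, the diversity requirement playing the same
anti-artifact role as the 3-phyla rule. Everything else is `unknown`.

One consequence is biologically meaningful: a tree in which the focal and
companion genera sit sister to a bacterial clade *at the root*, with no
other archaea anywhere, yields `unknown` direction — there is no outgroup
to orient the transfer — yet such trees are the strongest circumstantial
case for bacterial origin. These are captured by the **only-archaea
rescue**: status ≠ non-LGT, direction unknown, and every archaeal leaf on
the tree belongs to the focal species or companion genus. Rescued genes
are counted as bacterial-origin in the consensus totals.

### Bootstrap tiers

The inspected branch is the edge separating the focal lineage (the
focal+companion clade, or for a bare focal leaf the clade of focal plus
its sister) from the rest of the tree. Its support is binned: high
(> 70), moderate (51–70), low (≤ 50), absent. The value 50 is not covered
by the moderate band's published definition; it is binned low, and the
boundary is configurable.

### Consensus of two methods

A gene is `LGT_confirmed` only when both classification sets (typically
NJ-based and ML-based) call it LGT; genes whose alignments were too small
for the second method are `unresolved_too_few_taxa` and excluded from
confirmed totals. Final direction is the one resolved direction if
exactly one method resolves it, the shared one if both agree, and a
conflict flag (excluded from origin totals, surfaced for review) if they
disagree — no conflict case occurs in the published counts, so no
tie-break is invented. Origin calls: bacterial when the final direction
is bacteria→archaea *or* either method rescued the gene; eukaryotic and
archaea-export analogously. The summary exposes raw tier × direction ×
rescue cross-tabulations so any grouping of the counts can be recomputed
downstream rather than hard-coded.

## Codon metrics

Both metrics use the bacterial/archaeal genetic code (translation
table 11: nine two-fold, one three-fold, five four-fold, three six-fold
degenerate amino acids). Codons containing N are skipped and counted; a
terminal stop is trimmed; internal stops are an error in strict mode.

**CAI.** Relative adaptiveness w(c) = count(c) / max synonym count over
the highly expressed reference set, with 0.5 substituted for zero counts
before normalization (the standard convention; the weights match
Biopython's implementation exactly, which the tests cross-check). An
amino acid entirely absent from the reference gets w = 1 (neutral). CAI
is the geometric mean of w over the gene's codons, excluding Met, Trp and
stops, whose codon is not a free choice. Note CAI of a gene against its
own usage is 1 only if the gene is maximally biased (one codon per amino
acid); it is strictly below 1 otherwise.

**ENC.** Per amino acid observed n ≥ 2 times, F̂ = (nΣp² − 1)/(n − 1);
amino acids with F̂ ≤ 0 or n < 2 are excluded from their degeneracy-class
mean. ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61]. A
missing three-fold class (no Ile) is estimated as 1/(2/F̄₂ − 1/F̄₄),
falling back to (F̄₂+F̄₄)/2 when that expression is non-positive; a
missing six-fold class borrows the four-fold mean; a missing two- or
four-fold class means the sequence is too short and is an error. These
interpolations are conventional but not unique; they are configurable in
the sense that the functions are small and pure, and no claim is made of
bit-for-bit agreement with any particular legacy implementation.

**Background and flags.** Means and standard deviations (ddof = 1) are
computed over the genome-wide metric list minus the CAI reference genes
(whose usage defines w and would bias the background), requiring ≥ 10
genes. Flags mark genes strictly beyond ±2 SD. A background SD below
1e-9 (relative) is treated as zero and flags are suppressed with a
warning.

## Ancestral gene content

Ancestral presence/absence of gene families on a rooted species tree is
inferred per family by parsimony; the published analysis used a
co-evolution-aware reconstruction whose network inputs (protein
interaction and metabolic proximity data) are external resources, so this
package deliberately substitutes plain weighted parsimony and documents
it as such. Modes: `fitch` (unit costs, computed by the binary Sankoff
dynamic program), `dollo` (one gain; a node is present iff it lies on the
minimal subtree connecting the present leaves), and `weighted` (gain
costs `gain_penalty` × loss cost; default penalty 2.0, encoding that for
accessory families gain — usually lateral acquisition — is rarer than
loss). Ties at the root and in backtracking resolve toward absence:
families are assumed gained later rather than ancestrally ubiquitous.
Events are read off parent/child state changes and reported per branch;
`branch_diff` gives the gained/lost sets between a node and any ancestor
(the node-11 vs node-13 style comparison).

## Synthetic data

The generators provide the statistical structure each stage assumes, with
machine-readable truth, so the full pipeline is testable without any
sequence database.

**Gene trees.** Five scenarios (vertical, recent bacterial LGT, ancient
pre-divergence LGT, eukaryotic LGT, archaea export) are built as explicit
topologies: an ingroup implementing the scenario and a distant outgroup
clade on a long (2.0) stem, so midpoint rooting deterministically
separates them; internal edges are 0.05–0.15. Defaults — 6 bacteria over
3 phyla, 4 archaea, 3 eukaryotes — give 8–12-leaf trees, the scale at
which every rule (including the two-level nesting requirement) is
exercised. The inspected branch's bootstrap support is drawn from a
truncated normal (mean 75, sd 15, clamped to [0, 100]) so all three tiers
occur; other edges get 90–100. Bacterial phyla and genera come from a
fixed gut-community palette (Firmicutes, Bacteroidetes, Proteobacteria,
…) so donor-attribution reports look like real screens. The generator
returns the expected classification; with zero topological noise the
classifier recovers it exactly, which is a test of rule consistency, not
of robustness to phylogenetic error — real trees carry reconstruction
noise, paralogy and incomplete taxon sampling that these scenarios do not
emulate.

**Coding sequences.** Amino acids are drawn uniformly over the 18
multi-codon amino acids; each codon is drawn from α·host + (1−α)·donor
frequencies normalized within its amino acid. α = 0 models a fresh
transfer, α = 1 full amelioration. `biased_codon_freqs(bias, seed)`
interpolates uniform usage toward a single seed-chosen preferred codon
per amino acid. Real genes differ (non-uniform amino-acid composition,
GC pressure, length variation); the generator supports monotonicity and
calibration tests, not realistic genome emulation.

**Presence/absence matrices.** Families evolve down the species tree
with per-branch event probability 1 − exp(−rate × length) for the
applicable transition, optionally capped per family. Events are never
placed on the two root-incident branches: a loss there produces the same
leaf pattern as a gain on the sibling branch, so planted histories would
not be identifiable by any method. All-absent families are redrawn.

## Numerical choices

* NJ ties on the Q criterion join the lexicographically smallest label
  pair; negative branch estimates are clamped to zero with the deficit
  moved to the sibling edge. On additive matrices NJ reproduces the
  generating topology and path lengths to 1e−9 (verified exhaustively
  for all 123 topologies with 4–6 leaves).
* Bootstrap resampling draws column indices only, so supports are
  invariant to taxon input order at fixed seed.
* All generators take integer seeds through `numpy.random.default_rng`;
  identical seeds give byte-identical outputs.

## Problem sizes in the test and acceptance runs

Classifier recovery uses 500 simulated trees; NJ recovery enumerates all
123 unrooted topologies on 4–6 leaves; amelioration monotonicity uses 50
genes of 300 codons at each of five α values (Spearman ρ over 250
points); Fitch-vs-enumeration uses ten families on eight random 4–6-leaf
trees; zero-homoplasy recovery uses 40 families on 10-leaf trees. These
sizes keep the whole suite under a few seconds while leaving each check
statistically unambiguous.

## Limitations

The screen shares the fundamental caveats of sister-group LGT detection:
it is conservative (a transfer whose donor clade is poorly sampled, or
that involves a lineage like *Methanosarcina* rich in bacterial genes,
will be missed or left direction-unknown), midpoint rooting can misroot
trees with strong rate heterogeneity, and bootstrap tiers quantify only
topological support on one branch. The parsimony reconstruction ignores
branch lengths and co-evolution between families. The published-screen
fixture reproduces the printed per-category counts exactly but is an
encoding of those counts, not a re-analysis of the underlying alignments.
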