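# Methods

`limclass` reconstructs the evolutionary classification of the LIM protein
superclass: it turns per-protein domain annotations and LIM-domain gene
trees into homology groups, class/family assignments, and a gain/loss map
on a species tree. This note documents the models and procedures, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the procedure was genuinely
open.

## The pipeline

**1. Domain annotation.** Profile-HMM hits (read from HMMER per-domain
tables, or produced live with pyhmmer) are filtered on the *independent
E-value* — the per-domain significance computed as if the domain were the
only hit in the sequence — at a threshold of 0.05. A hit exactly at the
threshold is retained (the exclusion rule is "above 0.05", read
literally). Overlapping domain *envelopes* (the coordinate interval the
HMM considers plausibly part of the domain; 1-based inclusive throughout)
are resolved greedily per overlap cluster: repeatedly keep the hit with
the lowest independent E-value (ties: lower envelope start, then model
name) and discard everything overlapping it, where any shared residue
counts as overlap. This equals the exhaustive choice, among maximal
conflict-free hit subsets, of the one with the lexicographically smallest
sorted E-value sequence — the property the acceptance checks verify.

Accepted LIM hits become ordered *LIM-domain instances*: insert-state
residues (lower-case in the HMM alignment) are removed so every instance
carries a fixed-width match-state string; ordinals A, B, C… follow
amino-to-carboxyl order, and the gene-tree leaf label is
`<protein>.<ordinal>`. Two quality filters act on the match string:
instances that are more than 50% deletion columns are discarded as
truncated, and instances occupying fewer than 6 of the 8 canonical
zinc-coordinating positions with C/H/D/E are discarded as zinc fingers
mispredicted as LIM domains. Both thresholds are configurable — the
source analyses describe these filters qualitatively, so the numbers are
package defaults. Carboxy-terminal incompleteness below the truncation
threshold is kept as-is; missing columns are never imputed. Per gene, a
single representative isoform is kept (longest by default; ties go to the
lexicographically smallest id, making the choice order-independent).

**2. Homology groups.** Because deep backbone support in LIM gene trees
is typically poor, groups are defined from a *strict consensus*: the
multi-species gene tree is pruned to its human leaves (suppressing
degree-2 nodes and summing branch lengths, so path lengths among kept
leaves are unchanged) and intersected with the human-only gene tree. The
consensus cladogram contains exactly the bipartitions present in both
trees. It is rooted at its *topological* midpoint (every edge counted as
length 1) — the consensus has no meaningful branch lengths, so unit
lengths are the default, with projection of branch lengths available as an
option. When the midpoint falls exactly on a node the tree is rooted
there, yielding a root polytomy; ties between equally long leaf-to-leaf
paths are broken by the lexicographically smallest endpoint pair. Each
clade radiating from the root is a homology group; groups are numbered
deterministically (largest first, ties by smallest member label — the
numbering is arbitrary in the source analysis, so we fix one for
reproducibility).

Non-human LIM domains are assigned on the midpoint-rooted multi-species
tree by the nearest-neighbor rule: walk from the leaf toward the root to
the first ancestor whose subtree contains a human leaf; if all human
leaves under that node belong to one group, the leaf joins it, otherwise
it is unclassifiable. The set of groups observed under the deciding node
is always recorded, so the stricter reading of the rule can be audited;
no secondary "diverging just outside" rescue is applied.

**3. Motifs.** Classification motifs are scanned as regular expressions
over the 20-letter alphabet with `x` wildcards and character classes
(left-to-right, non-overlapping). The LD consensus `LDxLLxxL` is the
established one; the other shipped patterns (EPLIN 22-mer, PINCH 12-mer,
glycine-rich CRP motif, TMA1/TMA2, ZYX and ENIGMA motifs) are package
defaults with the published widths and positional behavior — motif
regexes are data, and real-proteome analyses should supply curated ones.

De novo discovery follows the masked iterative protocol: mask
low-complexity regions (builtin: windowed Shannon entropy, window 10,
threshold 1.5 bits — homopolymers and short tandem repeats score far
below, random windows far above) and domain envelopes with E ≤ 0.05; run
a single-motif finder; accept a motif if its E-value is ≤ 0.01 with at
least 4 supporting proteins; mask its occurrences; repeat until the first
rejection (an iteration cap, default 50, guards non-terminating
backends). A final pass over unmasked sequences may add occurrences of
existing motifs but never new motifs. The builtin finder is a ZOOPS
(zero-or-one occurrence per sequence) expectation-maximization over a
position weight matrix, deterministic under a fixed seed. Its
significance model is deliberately approximate: the summed site
log-likelihood ratio is corrected by each site's log alignment
multiplicity and a complexity penalty of 19w/2 nats (the likelihood-ratio
inflation from fitting 19 free frequencies per column) plus 2 nats per
site (absorbing best-subset selection), then converted to an E-value
against the number of scanned windows. The package is validated on
planted-site recovery and type-I control, not on agreement with any
external tool's E-values; external finders plug in as callables.

**4. Classification.** The 14 classes and their families ship as a
declarative signature registry (YAML): LIM count (or range), an ordered
N→C template of LIM slots, non-LIM domains and motifs, forbidden
elements, and spacing constraints. Four criteria are scored
independently: (1) LIM count, (2) homology-group complement, (3) group
order, (4) architecture (ordered-subsequence template match + forbidden
elements + spacing). A class is awarded when its *required* criterion
subset passes for some family. The source analysis states only that "a
reasonable subset" of criteria was required per class; the shipped
defaults are this package's reconstruction — group-anchored for classes
whose identity rests on LIM phylogeny (ABLIM, PXN, PINCH require groups),
architecture-anchored for the rest — and are user-configurable.

Group complements are anchored on human proteins: a first pass classifies
humans on architecture alone (group criteria waived — humans define the
reference), the modal group sequence per family becomes the expected
complement, and a second pass scores everyone. If a class has no human
exemplar with group data, its group criteria are waived with an evidence
note. Among classes whose required criteria pass, the winner is the one
matching the most template elements (then most required elements, then
most criteria); an exact tie leaves the protein UNCLASSIFIED with the tied
classes recorded — no arbitrary pick. Template elements marked optional
(e.g. the ABLIM VHP domain, the ENIGMA ZM/AM motifs) tolerate absence
with a `partial_architecture` flag, mirroring degraded architectures such
as placozoan ABLIMs without VHP. Under the default signatures a bare
single-LIM protein matches no class: LMO7 requires its CH anchor, so
relatives that lack it (like the fly LMO7-like protein) need group
evidence and a relaxed signature to classify — a deliberate conservative
default. Spacing constraints encode the rigid LASP geometry (first
nebulin repeat at residue 67 exactly, second at 102 ± 3, LIM start at
5–6), motif adjacency (EPLIN motif within 5 residues of the LIM, PINCH
motif within 2 residues of LIM E, TMA1–TMA2 gap of 17–18) and the
"closely spaced" ZYX LIMs (inter-LIM gap ≤ 15 residues; no number is
published, so this is a configurable default). Proteins whose LIM content
(identical aligned strings) is a proper subset of a same-species
protein's are flagged as suspected misannotations (partial isoforms); the
rule is within-species only and flags, never removes.

**5. Origins and losses.** Classification results become a class/family ×
species presence matrix with states present / partial / absent (partial =
only flagged, degraded architectures in that species — the half-filled
squares of presence/absence figures). Under single-gain (Dollo)
parsimony each row is explained by one gain on the stem edge of the MRCA
of its present species plus losses on the deepest edges whose entire
subtended leaf set lacks the character; for a single-gain model this loss
set is the unique minimum, which the acceptance oracle verifies by
exhaustive search. `treat_partial` defaults to `present` (a degraded
architecture still evidences the class); switching it to `absent` can
only move the origin tipward. The default nine-species tree follows the
ParaHoxozoa hypothesis — `(Co,((Sr,Mb),(Aq,(Ml,(Ta,(Nv,(Dm,Hs))))))` —
with the Porifera/Ctenophora order configurable, since metazoan-stem
conclusions do not depend on it. Out-of-dataset evidence (e.g. plant
CRPs, fungal PXNs) belongs in user-supplied extra columns, not code.

## Synthetic data: what it emulates and what it does not

The generator plants, under one integer seed (sub-generators draw from
independent digest-derived streams, so outputs are bit-identical across
runs and platforms):

* proteins realizing each class's canonical family template — LIM slots
  filled from per-homology-group consensus sequences of width 55 (the
  LIM domain is 50–65 residues) with the 8 zinc-coordinating positions
  fixed to the canonical C/H/D pattern and other positions mutated at
  rate 0.08 per copy; non-LIM domains as labelled hit intervals with
  log-uniform E-values (10⁻²⁵–10⁻⁶ for LIMs); motifs as regex-conformant
  substrings at template-consistent offsets, including the exact LASP
  spacing;
* decoy zinc-finger hits overlapping LIMs (E-values 10⁻⁴–0.04: they pass
  the E-value filter and must be removed by overlap resolution, emulating
  mispredicted zinc fingers);
* gene trees in which each homology group — one group per (class, LIM
  slot), shared across species — forms a clade on a long stem, with
  configurable NNI topological noise; and tree *pairs* (one random, one
  star backbone, identical within-group topologies) whose human-restricted
  strict consensus provably collapses the backbone while retaining every
  group clade, emulating a consensus with unsupported deep structure;
* presence matrices implied by canonical planted (origin, losses) events,
  which the Dollo mapper must invert exactly.

Default study conditions: all 14 classes, one protein per class per
non-human species and three human paralogs — multi-paralog human
complements are what real data shows, and three equal-size human groups
per class also place the consensus's topological midpoint on the central
node, so basal clades equal planted groups at zero noise. Noise knobs:
`arch_dropout_p` (template-element dropout), `extra_domain_p` (decoy
rate), `tree_nni_moves`.

What is *not* simulated: realistic sequence evolution (indels, rate
heterogeneity, alignment error), external-tool score distributions,
isoform structure, and gene-model errors. Passing recovery tests
therefore demonstrates that the pipeline's logic inverts its own
generative model perfectly and degrades monotonically with noise — not
that real proteomes will classify at these rates.

## Numerical choices and degenerate inputs

* Coordinates 1-based inclusive everywhere; all writers state this.
* Midpoint-location tolerance 1e-9 (exactly-on-node vs inside-edge).
* All tie-breaks are deterministic and documented above; classification
  is independent of protein input order, assignment of one leaf never
  depends on other non-human leaves.
* Empty inputs return empty outputs (no errors); an all-absent presence
  row returns a no-origin sentinel; an all-masked motif input returns a
  no-motif sentinel; negative E-values and inconsistent match-string
  widths are rejected as malformed.
* Problem sizes in the test and acceptance runs (20 seeds for recovery,
  200 oracle instances, 100 Dollo rows and midpoint trees, 10 + 20 motif
  runs, ≤ 10-leaf oracle trees) are the package's chosen desk-scale
  conditions: large enough to exercise every branch of the logic, small
  enough to re-run on a laptop in minutes.

## Known limitations

* The reproduction mode (`limclass reproduce`) needs the deposited
  supplementary gene-tree files; without them it is exercised against
  synthetic stand-ins only, and the published headline counts (38 groups,
  392/473 assigned, 206/265 classified) are displayed for side-by-side
  comparison, never recomputed from anything but user-supplied files.
* Required-criteria subsets, the ZYX gap, the truncation and zinc-filter
  thresholds, and all non-LD motif regexes are reconstructions or
  defaults, not published values; they ship as data so users can replace
  them.
* The builtin motif finder is a desk-scale tool; for real discovery use
  an external finder through the pluggable backend.
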