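# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `aprphylo`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Reference curation

The reference set is a two-subunit amino-acid alignment (AprB, AprA) with
per-record metadata (taxonomy, metabolic role reductive/oxidative, Apr
lineage I/II). Records are partitioned by **ungapped** sequence length with
strict inequalities: *core* requires AprB > 101 and AprA > 554 residues;
records failing that but with AprA > 118 residues are *shorter*; the rest
are rejected. The "more than N residues" phrasing of the thresholds is the
reason the inequalities are strict (a length of exactly 101 does not
qualify).

Subunit alignments are concatenated row-wise for records carrying both
subunits; the column where AprA starts is recorded as the boundary.
`mask_incomplete_columns` then retains only columns in which **every** row
has one of the 20 unambiguous residues. Gaps (`-`), missing markers (`.`,
normalized to `-` on input) and — by default — ambiguity characters
(X/B/Z/J/U/O) all disqualify a column; how ambiguity characters should be
treated during column elimination is genuinely underdetermined, so the
`treat_x_as_missing` flag can relax this. Masking is idempotent and
commutes with concatenation. On a full-scale curated reference this
procedure yields on the order of 82 comparable AprB and 503 comparable
AprA columns, which is also the default width of the synthetic generator.

## Distances and trees

Pairwise distances use the observed proportion of differing residues *p*
over *comparable sites* (positions where both rows are unambiguous), with
the Poisson correction d = −ln(1 − p) as the default model. Two deletion
modes exist: *complete* (drop every column not unambiguous in all rows;
used for reference-tree distances, where it is a no-op after masking) and
*pairwise* (per-pair comparable sites; used for OTU distances over
partially overlapping amplicons, where complete deletion across hundreds
of fragments would discard nearly everything). p ≥ 1 makes the correction
undefined and is an error unless an explicit cap is configured.

Trees are built with Saitou–Nei neighbor joining (Q criterion).
Determinism: the minimizing pair is the smallest (i, j) index pair in the
working matrix, and negative branch lengths are clamped to zero with a
warning. Trees are unrooted, stored with a trifurcating root; that choice
is invisible to bipartitions, Fitch scores and Newick output.

Branch support comes from a nonparametric bootstrap: columns of the masked
alignment are resampled with replacement, an NJ tree is rebuilt per
replicate (default 100 replicates), and the support of each internal
bipartition of the point-estimate tree is the percentage of successful
replicates containing it. Replicates whose resampled matrix is degenerate
are skipped and counted. The **consensus tree** construct overlays a
second analysis's supports onto the primary topology: every internal edge
carries `(primary, overlay)` supports, written in Newick as `85/72`
internal labels with `NA` for bipartitions absent from the secondary set.
Only NJ is implemented as a tree builder, so the default pairing is a
Poisson-model primary with a p-distance overlay; maximum-likelihood (JTT)
distances and parsimony tree *search* are out of scope by design — the
overlay construct, not any particular inference engine, is the point.

## Fitch parsimony and placement

`parsimony_score` is Fitch small parsimony over unordered amino-acid
states, vectorized over columns with 20-bit state masks. A gap or
ambiguity character at a leaf is missing data and contributes the full
wildcard state set. With a trifurcating root, sequential pairwise
combination at the root equals rooting on the edge to the last child, so
the score is exact for unrooted binary trees (verified against exhaustive
labeling enumeration).

Placement maps a raw fragment into reference coordinates by semi-global
alignment (no end penalties on either side) against the reference
consensus row — the column-wise modal residue over masked columns, ties to
the alphabetically smallest. Scoring: match +1, mismatch 0, gap open −5,
gap extend −1 (configurable). Fragments covering fewer than 50 masked
columns (configurable) are rejected as insufficient overlap.

Each query is then attached, in turn, to every edge of the fixed reference
tree, scored only over its covered columns. The per-edge score increase is
computed from directional Fitch sets: with D(v) the downward set below the
edge and U(v) the set of the rest of the tree, the edge set is
F = D∩U if non-empty else D∪U, and attaching a query with state q costs
exactly [q ∩ F = ∅] in that column. One postorder plus one preorder sweep
therefore scores all 2n−3 edges at the cost of two Fitch passes; the
result equals brute-force rescoring of every extended tree (tested on
random instances). Ties share the minimal delta and are broken by the
first edge in preorder — interactive insertion tools do not document their
tie handling, so a deterministic rule was chosen. Batch placement defaults
to *independent* mode (every query against the pristine reference;
order-invariant and reproducible); *sequential* mode, where each insertion
augments the tree seen by later queries, is retained for fidelity to
interactive tools. The reported pendant length, delta/covered-columns, is
display-only.

## OTU clustering

Clone libraries are translated with the standard code; frame `auto` picks
the frame (both strands) minimizing internal stop codons, ties to the
lowest-numbered forward frame, trailing partial codons dropped. Clones
with internal stops in their best frame, or covering fewer than 50 masked
columns after mapping, are excluded with a logged reason — the analog of
excluding amplicons that do not cover the amplified region.

Clustering is agglomerative with a distance cutoff (default 0.02
substitutions/site): repeatedly merge the pair of clusters with the
smallest inter-cluster linkage distance while it does not exceed the
cutoff. Linkage options are furthest, average (default) and nearest;
average is the default because era-typical OTU tools defaulted to average
neighbor, but the exact linkage used in published analyses is usually
unstated, so all three are exposed. Determinism: ties break on the
smallest pair of first-member indices; OTU ids are assigned by decreasing
size. Representatives are drawn uniformly per OTU from a seeded generator.
The output matches an independent hierarchical-clustering implementation
(scipy) cut at the same height, for all three linkages.

## Primer coverage

A degenerate primer (IUPAC codes, 5′→3′) is scanned across every window of
the template — the given strand for forward primers, the reverse
complement for reverse primers. A position mismatches when the template
base is not in the primer base's degeneracy set; the best site is the
minimal-mismatch window, ties to the leftmost on the scanned strand, with
the position reported 1-based on the input strand. Zero mismatches holds
iff the window belongs to the primer's degenerate expansion. Whether
published mismatch counts were taken at a fixed annotated site or a best
window is typically unstated; the best window is assumed, which can only
undercount. There is no 3′-anchoring or thermodynamic model — coverage is
pure mismatch counting. Mismatch bins default to 0 / 1–2 / 3–4 / ≥5. The
amplified region is the inter-primer interior (primer sites excluded,
as cloned inserts are primer-trimmed), which for a ~330 nt *aprA* amplicon
interior gives the ~110 comparable residues that motivate the whole
placement approach. Primer sequences are configuration inputs and are
never hard-coded.

## Group definition and assignment

Curator-supplied groups (a leaf → group map; names Re\*/Ox\* imply
reductive/oxidative roles) are realized on the reference tree rooted at
the midpoint of its longest edge — unrooted trees need a root for clade
semantics, and the longest edge is the conventional basal split. Each
group's clade is the subtree under the MRCA of its members; its edge set
is every edge inside that subtree plus the stem edge (stem attachments
count as inside). A group whose MRCA clade contains foreign leaves is kept
but flagged non-monophyletic.

A placed query is assigned to the group whose edge set contains its
attachment edge. When definitions are nested — an outer non-monophyletic
group's MRCA clade swallowing an inner group, which happens routinely on
estimated trees with short backbone edges — the innermost clade wins if
the hits form a chain under set inclusion; attachments on edges separating
groups, inside no clade, or hitting incomparable clades are
"unclassified", the stand-in for the manual "miscellaneous" handling such
analyses otherwise need. Counts are aggregated clone-wise (an OTU of five
clones contributes five to its group/library cell) with per-library
reductive/oxidative fractions.

For the comparison that motivates consensus-tree placement, a de-novo NJ
tree is built over the partial (mapped) columns only, with
pairwise-deletion Poisson distances, and each query is classified by the
reference membership of its smallest enclosing clade; concordance between
the two strategies is reported OTU-by-OTU.

## Synthetic data

The generators produce the statistical structure the analysis assumes, not
realistic sequences:

* **Reference sets** — random binary topologies grown by pairwise joining
  within groups and along a backbone, so the Re\*/Ox\* groups are
  monophyletic by construction; backbone edges are drawn three times
  longer than within-group edges (default within-group mean 0.08
  substitutions/site) so between-group separation dominates and the
  longest edge falls on the backbone. Sequences evolve from a random
  ancestral protein with Poisson(branch length × sites) substitutions per
  edge, each to a uniformly chosen different residue. The uniform
  (Poisson) replacement model is deliberate: it matches the distance
  correction being tested and keeps closed-form expectations exact, at the
  price of realism (no JTT-like exchangeabilities, no rate heterogeneity,
  no indels). Defaults: 32 taxa, 6 groups, 82 + 503 columns.
* **Query fragments** — contiguous 110-column windows from random leaves
  with Bernoulli substitutions (divergence ≥ 0.5 is rejected as outside
  the placement-recovery regime).
* **Clone libraries** — amino-acid centers separated by more than twice
  the clustering cutoff, mutated per clone at the requested intra-OTU rate
  with the per-clone substitution count capped at ⌊2 × rate × length⌋ so
  intra-center pairwise divergence stays bounded and the planted partition
  is exact under any linkage, then back-translated with uniform synonymous
  codons (translation in frame is stop-free by construction). Library
  defaults (3 libraries × 40 clones, 5 centers, intra rate 0.005) are a
  desk-scale version of multi-lake clone-library studies (which run to
  ~1000 clones and ~250 OTUs); the statistical structure, not the size, is
  what the tests exercise.
* **Primer sites** — a concrete realization of the degenerate expansion is
  planted, then exactly k positions are flipped outside their IUPAC sets.
  The generator re-draws the realization until the best-window scan
  returns exactly k; if the surrounding template happens to contain an
  incidental better window, it refuses (callers redraw the template).

Everything is reproducible byte-for-byte from a single seed. What passing
synthetic tests do **not** show: robustness to alignment error, indels,
compositional bias, chimeras, or rate variation across sites and lineages
— real environmental libraries have all of these.

## Pipeline and problem sizes

The `run` pipeline executes curation → tree → primer/amplicon → mapping →
OTU → placement → classification, writes only plain-text formats (TSV,
FASTA, Newick, JSON) and a manifest with package versions, seeds,
parameters and sha256 checksums of all inputs and outputs; re-running a
config reproduces outputs byte-identically, and every excluded sequence is
logged with a reason. A stage failure aborts with the stage name, keeping
partial outputs.

Test and acceptance runs use desk-scale sizes chosen to keep the whole
suite in seconds while still exercising every code path at realistic
column counts: reference trees of 16–32 taxa, 200 placement trials,
oracle sweeps to 12 taxa (NJ), 6 leaves × 5 columns (exhaustive Fitch) and
8 sequences (clustering). Known limitations: no likelihood-based placement
or branch-length optimization, no chimera screening, no
diversity/rarefaction statistics, and nucleotide-level 16S workflows are
only covered insofar as the generic distance/clustering operations apply.
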