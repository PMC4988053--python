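# Methods

## Network model

A data-derived regulatory network (DDRN) is a directed graph *G = (V, E)*
over opaque gene-identifier strings (ENSEMBL ids by convention, but nothing
is enforced, so synthetic ids work).  The node set *V* is induced by the
edge set: isolated genes are not part of a network, which keeps "number of
genes" a function of the edges alone.  Edge identity throughout the package
is the ordered pair `(tf, tg)` — two edges are equal iff their gene pairs
are equal, and the attached evidence never distinguishes them.  This is what
makes the algebra well defined: union, intersection and difference operate
on edge-pair sets, while evidence records (binding sites with p-values and
TSS distances, ChIP peaks, literature PMIDs, transfer provenance) are
carried along and concatenated on merge.

An edge's **support** is the number of distinct source networks contributing
evidence to it, recomputed whenever evidence changes.  Union therefore
produces support values in `1..k` for `k` inputs, and
`support_filter(union(N1..Nk), k)` coincides with `intersect(N1..Nk)`
whenever the inputs carry distinct network ids (the property tests assert
exactly this form).  Bare imported edge lists without an evidence column get
one `Database` evidence record per row attributed to the network itself, so
the support invariant holds for them too.

## Coordinates

Internally every interval is 0-based half-open (BED convention); conversion
happens only at parse/write boundaries.  FIMO's 1-based inclusive
`[start, stop]` becomes `[start-1, stop)`; a GTF transcript's TSS is
`start-1` on `+` and `end-1` on `-`.  This single-convention rule is the
package's main defence against off-by-one errors, and a property test pins
`stop - start + 1` (source) = `end - start` (internal) for every FIMO row.

## Builders

A feature is credited to gene *g* for each TSS *t* of *g* (genes may carry
several TSSs, one per annotated transcript) when the feature interval
intersects the **closed** window `[t-w, t+w]`.  Any-overlap is the most
permissive reading of "within ± w bp"; a `midpoint_only` flag offers the
stricter alternative.  Defaults: *w* = 5,000 bp for human/mouse and 500 bp
for worm/fly; PWM-hit p-value threshold 10⁻⁵ (standard) or 10⁻⁶
(high-confidence), compared inclusively (`p ≤ threshold`), so a hit exactly
at the threshold is kept.  The signed TSS distance stored in evidence is
the feature's integer-floor midpoint minus the TSS, sign-flipped on minus
strand genes so positive always means downstream; the convention is ours —
the quantity is only ever filtered by absolute value, so the choice of sign
is cosmetic but fixed.

The open-chromatin builder keeps a hit only if accessible chromatin
supports it: plain mode requires intersection with any open-chromatin peak;
footprint mode uses only peaks whose length lies in 6–40 bp (the digital
genomic footprint range) and requires the hit to lie fully inside one.  The
result is a subset of the TFBS network by construction, and footprint-mode
edges are a subset of plain-mode edges.

Window lookup uses an interval tree (windows as `[t-w, t+w+1)` tree
intervals, which reproduces closed-window intersection exactly); the test
suite holds it contract-equal to a brute-force all-pairs scan.  Hits whose
matrix has no TF mapping are tolerated and tallied in a diagnostics counter
rather than raised — real PWM collections routinely contain unmapped
matrices.

## Algebra and filters

Orthology transfer maps each edge to the cross-product of its endpoints'
orthologs; edges with an unmapped endpoint are dropped and counted.  The
default policy is `all_pairs`; `one2one_only` treats genes with other than
exactly one ortholog as unmapped, for conservative analyses.  Transferred
edges carry `Transferred` evidence, one record per distinct origin source
network, so support survives the transfer; a bijective map composed with
its inverse is the identity on edge sets.

The binding-site filter evaluates criteria conjunctively **within one
evidence record** (p-value and |TSS distance|, both inclusive) and keeps an
edge if **any** record satisfies them all — an edge is as good as its best
binding evidence.  Records lacking a filtered attribute fail that criterion,
so a literature-only edge does not survive a p-value filter.  Surviving
edges retain only their satisfying records.  All filters are monotone:
tightening a parameter never adds an edge.

## Repository and faceted browsing

The repository is a plain directory (edge-list TSV + metadata JSON per
network, a JSON index, one ontology TSV per dimension) rather than a
database server — portability and diff-ability over scale; single-writer by
design.  Networks are indexed on seven metadata dimensions; each dimension's
ontology is a forest (flat value lists are depth-1 forests), and values not
present in an ontology are auto-created as root nodes on registration.  A
record matches a selected node iff its assignment is that node or a
descendant; records unassigned in a selected dimension never match.
`browse` lists, per unselected dimension, the top-level nodes with
descendant-inclusive counts, and hides dimensions where fewer than two nodes
match — only dimensions that still separate the remaining networks are
shown, which is what makes recursive drill-down converge.

The census arithmetic (`enumerate_derived_networks`) encodes how derived
network counts compose: per species, open-chromatin networks = open-chromatin
experiments × binding-site network variants + imported pre-computed
footprint networks; totals sum the five categories and then the species.
`ENCODE_CENSUS` ships the compendium's per-category counts as input data.

## Statistics

The two-group comparison is a Welch two-sample, two-sided t-test (unequal
variances, Welch–Satterthwaite degrees of freedom) via
`scipy.stats.ttest_ind(equal_var=False)`; Welch is the safe default for
unequal group sizes and variances.  Degenerate input — both groups constant —
returns t=0, p=1 at equal means and t=±∞, p=0 otherwise.  No
multiple-testing correction is applied across metrics or repeated
comparisons; callers comparing many metrics should correct externally.
Sub-network overlap divides by the full reference edge set, counting
reference edges absent from the compared network's gene space as misses, so
fractions remain comparable when one reference is held against many
networks.  Self-loops count once toward total degree; normalized degree
divides by |E| and is undefined (an error) for empty networks.

## Synthetic scenarios

The generator emulates the geometry and statistics of promoter-proximal
binding evidence, not sequence: genes sit at TSSs spaced `tss_spacing_bp`
apart (default 20,000 bp, which keeps ±5,000 bp windows disjoint and leaves
inter-gene gaps for decoy placement) on one toy chromosome per species; a
`multi_tss_rate` fraction of genes (default 0.2) get 2–5 TSSs, as real genes
do.  A truth edge set is drawn at `edge_density` (default 0.15) over
TF × genes with `n_tfs` = 6 of 30 genes by default — sizes chosen so that
scenarios exercise multi-edge genes and multi-target TFs while remaining
instant to build.  For every truth edge the generator plants ≥1 motif hit
inside the window with p-value log-uniform in (10⁻⁹, 10⁻⁶ ⁰⁵), i.e.
strictly below the high-confidence threshold, so the same truth is
recoverable at both standard thresholds; ChIP peaks (200–400 bp) are placed
inside truth-edge windows for every TF; open-chromatin peaks are built
around a coverage-sampled fraction (`open_fraction`, default 1.0) of truth
hits, padded to stay within the 6–40 bp footprint range with the hit fully
contained.

Decoys (`decoy_hit_rate` per gene, Poisson, default 1.0) come in three
flavours, none of which may create an edge: above-threshold hits inside
windows, good hits placed in the inter-gene gaps outside every window, and
good in-window hits from a matrix absent from the motif map.  The
open-chromatin truth is computed post-hoc by the containment rule over the
generated peaks, so it is exact for the footprint builder at any coverage;
at `open_fraction` = 1 it equals the TFBS truth and both overlay modes
recover it exactly.  With two species, the second species' truth is defined
as the orthology transfer of the first (orthologs one-to-many at
`ortholog_one2many_rate`, default 0.1), making cross-species consistency
true by construction.

All randomness flows through one seeded NumPy generator; identical
parameters and seed give byte-identical files.  If the requested geometry
leaves no room for out-of-window decoys (or the stated chromosome length
cannot hold the genes), generation fails with an error suggesting larger
`chrom_length_bp`/`tss_spacing_bp` rather than silently bending the rules.

What passing tests on these scenarios shows: the builders implement their
window/threshold/overlay contracts exactly, and the algebra obeys its laws.
What it does not show: robustness to real-data pathologies — overlapping
promoter windows of neighbouring genes, peak-calling noise, motif hits
correlated with GC content, assembly gaps — none of which the generator
emulates.

## Test and acceptance problem sizes

The property suites run at deliberately modest sizes — up to 10³ features ×
10² genes for the assignment oracle (200 random scenarios), 500 random
network pairs for the algebra laws, 100 seeded scenarios of 15 genes for
exact truth recovery, 100 random transfer cases, repositories of up to 100
networks for faceted browsing — chosen so the full suite completes in
seconds while still exercising every contract; the properties asserted are
size-independent.  `scripts/acceptance.py` uses 25 two-species scenarios of
20 genes and reports aggregate edge-exact recovery fractions (a built edge
set differing from truth in either direction lowers the fraction below 1).

## Known limitations

* Promoter-window assignment only: no enhancer or long-range interactions.
* No peak calling and no PWM scanning; the package consumes peak and
  FIMO-style hit files.
* Motif-hit strand is recorded but ignored for edge inference.
* Edge support counts distinct source-network ids; unioning a network with
  itself does not raise support.
* The repository has no locking; concurrent writers will corrupt the index.
* GO-based gene-set filtering is not built in: callers supply gene lists.
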