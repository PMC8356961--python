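# Methods

This note records the models, conventions and numerical choices behind
phylokit, and what the synthetic-data generators do and do not emulate.

## Tree model and Newick dialect

A tree is rooted in the biological sense iff its root has exactly two
children; a higher-degree root marks an unrooted tree (standard Newick
convention — there is no explicit rooted flag).  Branch lengths and
supports live on the edge above a node.  The parser follows the dialect
dominant in bootstrap pipelines: an internal-node label that parses as a
finite number is stored as the branch support of the edge above; any
other label is kept as an internal node name.  A node therefore carries a
support or a name, not both — files that use internal labels for clade
names *and* encode supports elsewhere are outside this dialect.

Square-bracket comments are skipped, not preserved (quoted labels may
contain brackets; the stripper is quote-aware).  Labels containing
whitespace or Newick metacharacters are single-quoted on output with `''`
escaping; underscores are never translated to spaces, avoiding the
classic underscore ambiguity.  Numbers are written in their shortest
round-trippable decimal form, with positional notation guaranteed for
magnitudes ≥ 1e-4.  gzip is detected by magic bytes only — extensions
lie too often in pipelines.

## Alignment model

Sequences are stored uppercase; `U` is normalized to `T` in nucleotide
data so one code path serves the distance estimators (the original symbol
is not preserved).  `?` and `*` are kept on read; `?` is treated as
missing by analyses.  Alphabet auto-detection calls data nucleotide when
≥ 90% of non-gap characters are in `{A,C,G,T,U,N}`.  Duplicate names are
an error, never auto-renamed: silent renames corrupt downstream joins.
Phylip is read in both sequential and interleaved layout (detected from
line structure) with relaxed names; sequential is written, which keeps
output deterministic.  A column is *constant* when all its unambiguous
non-gap characters are identical and at least one exists.

## Editing conventions

* Gap-fraction cutoffs (`clean sites|seqs`) compare strictly (`>`): at
  cutoff 0.5 a column exactly half gaps is kept.  Ambiguity codes count
  as non-gap.
* The API is 0-based half-open everywhere; the CLI accepts the 1-based
  inclusive convention users expect and converts.
* `translate`: codon `---` → `-`; any other codon containing a gap or
  ambiguity → `X`; stops → `*`; a 1–2 nt trailing remainder is dropped
  with a reported count.  Shipped genetic codes: standard and vertebrate
  mitochondrial.
* `codonalign` verifies per sequence that the coding sequence translates
  to the ungapped protein row (a trailing stop codon is tolerated) and
  reports the first mismatching residue.  `translate ∘ codonalign` is the
  identity on the protein alignment, which the tests enforce over random
  fixtures.
* `seqboot` draws replicate *r* from a stream seeded by `(seed, r)`, so
  any single replicate is reproducible without generating its
  predecessors.

## Distance estimation

Nucleotide estimators are the published closed forms evaluated from the
pairwise proportions of A↔G transitions (P1), C↔T transitions (P2) and
transversions (Q), with pairwise deletion of sites carrying a gap or
ambiguity in either sequence (no fractional matching of ambiguity codes).
Base frequencies for F81/F84/TN93 are estimated once from the whole
alignment rather than per pair: per-pair frequencies are noisy on short
overlaps and make the matrix depend on deletion patterns.  This can
differ slightly from per-pair implementations on strongly heterogeneous
data.  A non-positive logarithm argument (saturation) yields +Inf with a
warning count; the Phylip matrix writer substitutes a sentinel of 20.0 so
downstream tools still get a numeric matrix.

Protein ML distances build the rate matrix `Q_ij = s_ij π_j` (i ≠ j, the
diagonal set to minus the row sum), normalized so `−Σ_i π_i Q_ii = 1` —
one expected substitution per unit branch length.  `P(d) = exp(Qd)` is
computed through the symmetric similarity transform
`B = D^{1/2} Q D^{−1/2}` (D = diag π) whose eigendecomposition is exact
and stable for reversible models and is precomputed once per model.  The
1-D likelihood is maximized with scipy's bounded scalar minimizer on
`[1e-9, 20]`, absolute tolerance 1e-8 on d; estimates at the lower bound
are reported as 0.  No rate heterogeneity across sites is modeled.  The
exchangeabilities and frequencies for DAYHOFF, JTT, MTREV, LG and WAG are
the published matrices, frozen as Python literals.

## Tree editing

* `prune` suppresses the degree-2 nodes left behind, summing branch
  lengths; when two edges merge, the support of the edge farther from the
  root is kept (deterministic provenance; taking the max would mix
  evidence from different splits).  Patristic distances among survivors
  are preserved exactly.
* Rerooting is one generic operation — place the root on an edge,
  splitting it at a given point — implemented by reversing parent
  pointers along the path to the old root.  Both halves of the split edge
  carry the original edge's support, since they induce the same
  bipartition.  Outgroup rerooting roots the edge above the minimal clade
  containing the outgroup, splitting it at its midpoint (the placement
  along the edge is a free choice; the midpoint is symmetric), and warns
  when the outgroup is not monophyletic.  Midpoint rooting bisects the
  longest tip-to-tip path; ties are broken by the lexicographically
  smallest tip-name pair.  Both preserve the unrooted bipartition
  multiset and the total branch length.
* `collapse` contracts internal edges strictly below the cutoff; edges
  without a support value are never collapsed under the support
  criterion; tip edges are never collapsed.
* `resolve` expands polytomies with zero-length, support-free edges;
  an unrooted root keeps degree three so the tree stays unrooted.
* Random trees: `yule` splits a uniformly chosen tip until the target
  size, with exponential(1) branch lengths (a length model had to be
  chosen; exponential(1) gives varied, strictly positive lengths).
  `uniform` inserts each next tip on a uniformly chosen edge including
  the root edge, which yields the uniform distribution over rooted
  binary labeled topologies — verified against the 1/105 frequency of
  each 5-tip topology.  `caterpillar`/`balanced` are deterministic unit-
  length shapes.

## Tree statistics

Sackin's index counts *edges* from root to tip (so a two-tip tree scores
2); Colless requires a strictly binary rooted tree and sums |L − R| over
internal nodes.  Both are reported absent for unrooted trees; raw
(unnormalized) values only.  Cherries are counted in the unrooted sense:
a bifurcating root is suppressed and nodes adjacent to exactly two tips
are counted, so the count is invariant under rerooting; trees of two or
three tips, whose unrooted forms degenerate, count one cherry.  The
patristic matrix accumulates child-subtree tip distances at each internal
node, meeting every tip pair exactly once at its MRCA.

## Splits, comparison and supports

Splits are canonicalized as the side *not* containing the
lexicographically smallest tip name, making equality orientation-free and
deterministic; the two edges flanking a bifurcating root induce the same
split and contribute once.  Multifurcating trees are compared with
asymmetric counts (reference-only vs comparison-only splits).

FBP and TBE hold each split as an integer bitmask over the sorted tip
set; a transfer distance is then an XOR plus popcount against every edge
(tip edges included) of the bootstrap tree, minimized over the two
orientations.  This optimized path is checked exactly against a naive
per-edge set-comparison oracle in the tests, on exhaustive small trees
and random 50-tip instances.  Bootstrap trees must carry exactly the
reference's tip set; partial overlaps are rejected rather than silently
renormalized.  Supports are written as internal-node labels with six
significant digits; per-edge diagnostics (light-side size p, mean
transfer distance δ̄) are available as TSV.  For a split exactly half the
tip set, the reported "light side" is the side not containing the
smallest tip name.

## Synthetic data

`simulate_pair` draws an ancestor from the model's equilibrium
frequencies and a descendant site-wise from `P(d)` — two sequences at a
known distance, site-independent, without indels, rate variation or
compositional drift.  `random_alignment` is IID uniform over the
alphabet with optional gap sprinkling.  Passing tests on these fixtures
demonstrates estimator correctness and invariance properties under the
models' own assumptions; it says nothing about robustness to model
violation in real data (selection, heterotachy, alignment error).
Problem sizes in the test suite — e.g. 10,000 sites for JC recovery,
50,000 for WAG recovery, 1,000 trees of 4–100 tips for round-trip I/O,
200 small plus 100 50-tip instances for the transfer-distance oracle —
were chosen so each check has clear statistical resolution while the
whole suite stays fast.

All randomness is seeded; per-case streams derive from `(seed, case)`
pairs so no result depends on generator call order.

## Known limitations

* PhyloXML, NHX annotations and Newick comment preservation are out of
  scope; bz2/xz containers are not read (gzip only).
* No nucleotide ML distances (closed forms only) and no Γ rate
  heterogeneity.
* Internal node names and supports are mutually exclusive per node.
* Support computation rejects bootstrap trees with missing tips.
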