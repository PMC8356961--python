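# phylokit

A Python toolkit for the recurring, error-prone data-manipulation steps of
phylogenetic workflows: converting alignment and tree formats, cleaning and
editing multiple sequence alignments, building bootstrap replicates,
estimating evolutionary distances, editing and summarizing phylogenetic
trees, comparing topologies, and computing bootstrap branch supports.  It
is aimed at people assembling phylogenomic pipelines (in shell scripts,
Nextflow, Snakemake, ...) who need small, atomic, chainable commands, and
at developers who want the same operations as a library.

It ships two command-line tools in the spirit of `git`-style subcommands:

* **`treekit`** — trees: `reformat`, `stats`, `prune`, `collapse`,
  `reroot outgroup|midpoint`, `rename`, `resolve`, `generate`, `matrix`,
  `compare trees|tips`, `compute support fbp|tbe`;
* **`alnkit`** — alignments: `reformat`, `stats`, `clean sites|seqs`,
  `rename`, `mask`, `extract`, `concat`, `translate`, `codonalign`,
  `build seqboot`, `compute distance`.

Every command reads standard input and writes machine-parseable results to
standard output by default (logging goes to standard error), so commands
pipe into each other.  gzip input is detected by magic bytes; `-o x.gz`
compresses output.

## What it computes

**Topology comparison.** Each internal edge of an unrooted tree induces a
bipartition (split) of the tip set.  Two trees on the same tips are
compared by their split sets; the Robinson–Foulds (bipartition) distance
is the number of splits found in exactly one tree.

**Bootstrap supports.** Given a reference tree and bootstrap trees, the
Felsenstein bootstrap proportion (FBP) of a branch *b* is the fraction of
bootstrap trees containing *b*'s exact split.  The transfer bootstrap
expectation (TBE) is

    TBE(b) = mean over bootstrap trees T of [ 1 − δ(b, T) / (p − 1) ]

where δ(b, T) is the transfer distance — the minimum number of tips that
must change sides to turn *b* into some branch of *T* — and *p* is the
size of *b*'s lighter side.  Since δ ≤ p − 1 always, TBE lies in [0, 1];
it equals FBP on cherries (p = 2) and never falls below it.  TBE is the
support of choice for large, noisy trees where exact split matches are
rare.

**Distances.** Nucleotide distances use the classical closed-form
estimators with pairwise deletion: JC, K2P, F81, F84 and TN93 (e.g.
`d_JC = −(3/4) ln(1 − 4p/3)`, `d_K2P = −(1/2) ln(1−2P−Q) − (1/4) ln(1−2Q)`
with P, Q the transition and transversion proportions).  Amino-acid
distances are maximum-likelihood estimates under the empirical models
DAYHOFF, JTT, MTREV, LG or WAG: the likelihood
`L(d) = Π_sites π_a P_ab(d)` with `P(d) = exp(Qd)` is maximized over
`d ∈ [1e-9, 20]` by bounded scalar optimization, with the rate matrix
normalized to one expected substitution per unit distance.

**Tree statistics.** Tip/edge counts, branch-length and support
summaries, number of cherries, Colless and Sackin imbalance indices,
patristic (path-length) distance matrices.

## Worked example

Generate a 5-tip Yule tree, ten bootstrap trees, and annotate the
reference with TBE supports:

```
$ treekit generate yule -n 5 --seed 42 > ref.nwk
$ for k in $(seq 100 109); do treekit generate yule -n 5 --seed $k; done > boots.nwk
$ treekit compute support tbe -i ref.nwk -b boots.nwk | treekit stats
tree  n_tips  n_internal_nodes  n_edges  sum_length  mean_length  min_length  max_length  mean_support  n_cherries  colless  sackin  rooted
0     5       4                 8        9.86376     1.23297      0.0792942   3.1243      0.2           2           6        14      true
```

The two non-trivial internal edges each get support 0.2: across ten
random bootstrap trees, the average normalized transfer distance to the
nearest branch leaves 1 − δ̄/(p−1) = 0.2.  The tree is maximally
unbalanced for 5 tips (Colless 6, Sackin 14) and has 2 cherries.

A K2P distance matrix straight from a FASTA stream:

```
$ printf '>s1\nACGTACGTAA\n>s2\nAC-TACGTAA\n>s3\nACGTTCGTAA\n' | alnkit compute distance -m k2p
   3
s1  0.00000000 0.00000000 0.10846615
s2  0.00000000 0.00000000 0.12172012
s3  0.10846615 0.12172012 0.00000000
```

s1 and s2 differ only at a gapped site, which pairwise deletion excludes,
so their distance is 0; s1 and s3 differ by one transition in 10 sites
(p = 0.1), giving the K2P correction 0.1085.

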