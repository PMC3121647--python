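# syntons

Exact detection of synteny blocks across multiple bacterial genomes, with a
gene quorum.

## The problem

Conserved blocks of genes ("syntenies", "gene teams", "gene clusters") mark
genomic regions under functional constraint — in prokaryotes, typically
operons.  Finding them across *n* genomes is hard when the gene-to-gene
homology relation is many-to-many and not transitive (as thresholded BLASTP
similarity is), when gene order within a block is freely permuted, when a
few unrelated "gap" genes interrupt a block, and when a block is simply
missing from some of the genomes.  Most multi-genome tools handle this with
greedy heuristics whose output has no closed-form definition.  This package
implements an exact alternative: a clear-cut combinatorial definition of a
block, and an algorithm that provably enumerates all of them.

## The model

Each genome *Gᵢ* is an interval graph: vertices are genes, and two genes
are neighbours when their rank distance is at most δ_gap (wrap-around on
circular replicons; δ_gap = g allows g − 1 intervening genes).  A symmetric
inter-genome relation *S* (e.g. BLASTP pairs with p ≤ 1e-10, identity ≥
40 %, alignment covering ≥ 80 % of the smaller protein) ties genes of
different genomes together.

An *n*-way correspondence is obtained by aggregating *S* under a topology
rule — **clique** (all pairwise related), **connected component**, or
**γ-quasi-clique** (every gene related to ≥ γ·(k−1) of the other k−1) —
giving *spines*: tuples with one gene (or gene set) per genome.  A quorum
*q ≤ n* allows spines to skip up to *n − q* genomes via *don't-care* slots.
Spines are the vertices of a Partial Network Alignment Multigraph (PNAM)
whose colour-*i* edges join spines with δ_gap-neighbouring genes on genome
*i*.  A **synton** is a maximal set of spines sharing one covered-genome
set *I* (|I| ≥ q) and connected on every colour in *I*; syntons form a
partition of the PNAM vertices.  A final ⊑ filter (gene-set subsumption
lifted to syntons) removes redundant low-coverage blocks.

The production engine never materialises the PNAM: it alternates SPLIT
(partition the current class into per-colour connected components) and
EXPAND (add the next genome, extending each partial spine by its terminal
genes or a don't-care) in a depth-first search.  A brute-force oracle —
explicit spine enumeration plus fixpoint refinement — verifies the engine
on hundreds of randomized instances in the test suite.

## Worked example

The bundled `F2` example has genomes `[a1, b1]`, `[a2, b2]`, `[a3]` and
S = {a1–a2, a1–a3, a2–a3, b1–b2}.  With clique spines and quorum 2:

```sh
syntons fixtures --name F2 --out-dir demo
syntons run --genes demo/genes.tsv --pairs demo/pairs.tsv \
    --quorum 2 --gap 1 --out-dir demo/out
```

prints

```
4 syntons (largest: 2 spines) -> demo/out
```

The five spines (a1,a2,a3), (a1,a2,\*), (a1,\*,a3), (\*,a2,a3), (b1,b2,\*)
partition into four syntons — three singletons and the two-spine block
{(a1,a2,\*), (b1,b2,\*)} that pairs the a- and b-genes on genomes 1 and 2.
Adding `--maximal-only` keeps the two syntons that are maximal under ⊑,
{(a1,a2,a3)} and the two-spine block, and reports `2 syntons`.
`demo/out/` also contains per-genome projections (gene lists, rank spans,
gap-gene counts) and, per S pair, the size of the largest synton containing
it.

Other subcommands: `syntons simulate` writes seeded instances with planted,
ground-truthed blocks; `syntons blast-filter` turns BLAST tabular output
into an S pair table; `syntons run --oracle` forces the brute-force
explicit-multigraph path for verification.

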