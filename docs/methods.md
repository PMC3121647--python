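# Methods

## Objects

**Primary graphs.** A genome is a rank-ordered gene list (ranks dense,
1..L).  Two genes of one genome are neighbours when their rank distance is
at most δ_gap; on circular genomes the distance is min(|Δ|, L − |Δ|).  We
follow the distance rule literally: δ_gap = g connects genes with up to
g − 1 intervening genes, so δ_gap = 1 is strict adjacency.  Practitioners
who think in "number of allowed gap genes" should pass gaps + 1.  Gene
strand is parsed from input tables but ignored by every algorithm: blocks
here are defined by proximity and correspondence, not orientation.

**Correspondence.** The relation S is symmetric, many-to-many and not
assumed transitive.  When derived from BLAST tabular input, a pair is kept
iff p ≤ 1e-10, percent identity ≥ 40 and the alignment covers at least 80 %
of the smaller protein (all three thresholds configurable); the relation is
symmetrised and self hits are dropped.

**Spines and quorum.** Spines aggregate S into tuples with one slot per
genome; a slot is a non-empty gene set or a don't-care mark.  Slots hold
*sets* so that one representation serves all aggregators: clique and
quasi-clique slots are singletons, a connected-component slot may hold
several genes of one genome.  The quorum q bounds don't-care slots by
n − q.  The quasi-clique degree rule counts covered genes only, mirroring
the clique rule's treatment of don't-care slots.  In clique and
quasi-clique modes *all* valid tuples are vertices, not only maximal ones:
a sub-clique of a larger clique is a distinct spine.

**Syntons.** Colour-i edges join spines whose slot-i genes come within
δ_gap; a shared identical gene (distance 0) counts.  This distance-0 rule
is adopted globally — without it two spines anchored on the same gene could
never join one synton, and the three-spine block of the bundled F1 example
would be unobtainable.  A synton is a maximal spine set with uniform cover
I (|I| ≥ q), connected on every colour of I *within the set* (never through
outside vertices).  Grouping by cover signature before refinement
implements the uniform-cover clause exactly; syntons then partition the
vertex set.

## Algorithms

**Oracle.**  Spines are enumerated explicitly (backtracking with clique
pruning; a broadcast tensor of within-tuple degrees for quasi-cliques;
S-components via networkx for CC mode), the multigraph's colour edges are
materialised from sorted rank occupancies, and each cover group is refined
to its common-connected-component partition by fixpoint splitting, one
colour at a time.  The refinement is order-independent; the suite checks
this over all colour permutations.  A second, edge-free refinement computes
colour components directly from sorted rank runs (two spines are adjacent
iff consecutive occupancies are within δ_gap) in near-linear time; the two
refinements are cross-checked against each other on random instances.

**Engine.**  The production path is the depth-first SPLIT/EXPAND recursion
over genomes.  SPLIT partitions a class on each processed colour in turn,
temporarily removing members with a don't-care at that colour and adding
them back to every resulting part — deliberate duplication across branches.
EXPAND grows each member by the next genome's terminals and, within budget,
by a don't-care.  Terminal computation uses a *necessary* condition with
dead-branch pruning, since the exact prefix-of-valid-spine test is
impractical: in clique mode a terminal must be S-related to every covered
gene of the prefix.  In quasi-clique mode the degree rule is not monotone
under extension (later genes raise degrees), so the engine prunes with the
sound relaxation deg(v) ≥ γ·(k′ + r − 1) − r for every covered gene v,
where k′ is the covered prefix size and r the number of remaining genomes;
at γ = 1 this reduces exactly to the clique rule, and full validity is
re-checked at finalisation.  Finalisation drops invalid tuples, splits
stable classes by cover signature, re-refines each group, deduplicates
syntons discovered in several branches, and asserts the partition property
(an internal-invariant failure aborts with a distinct exit code).  Engine ≡
oracle over the randomized grid is the package's central test.

Connected-component aggregation bypasses incremental expansion: its spines
are whole S-components, precomputed, and go straight to refinement.

**Filters.** The ⊑ subsumption filter (gene-set inclusion on spines, lifted
to syntons by ∀u₁∃u₂) is applied pairwise over the final partition, O(|P|²)
spine checks — fine at desk scale.  It runs before the min-size filter;
min_size counts *spines* per synton, a deliberate semantic choice (spines
play the role of anchor points; "size in genes" would differ for
connected-component slots).  The per-pair statistic records, for each S
pair, the spine count of the largest synton containing both genes; pairs in
no synton are excluded by default.

## Parameters

| parameter | meaning | default |
|---|---|---|
| δ_gap | neighbourhood radius in ranks (g ⇒ g−1 intervening genes) | 1 (CLI); 3 in the simulator, the usual functional-study setting |
| q | minimum genomes covered per synton | required, ≥ 2 |
| aggregator | clique / connected component / γ-quasi-clique | clique |
| γ | quasi-clique degree fraction | none (quasi only) |
| min_size | minimum spines per reported synton | 1 |
| spine_cap | live partial-spine / enumeration guard | 2 × 10⁶ |

The spine cap exists because the exact search grows exponentially on many
closely related genomes at low quorum; exceeding it raises a resource error
that suggests raising the quorum.

## Synthetic data

The generator plants operon-sized blocks — groups of gene families laid on
a chosen genome subset, each genome receiving the families contiguously, in
independently permuted order when requested, with gap genes interleaved at
a configurable rate — inside background genomes whose genes carry globally
unique family labels and therefore can never join a spine.  S connects
same-family genes across genomes; an edge-dropout rate breaks transitivity
(as thresholded similarity does in practice) and a paralog rate duplicates
block genes into background positions, making S many-to-many.  Everything
is reproducible from the seed.  Defaults (3 genomes of 40 genes, two
5-family blocks, permutation on, 10 % gap genes, clean S) describe a small
clean comparison; recovery tests vary sizes, subsets and gap rates up to
0.3 and use dropout 0 / paralogs 0 so that ground truth is unambiguous.

What the generator does *not* emulate: realistic evolutionary processes
(inversions, transpositions, tandem duplication, sequence-level
divergence), genome-size heterogeneity, or biased gene-family size
distributions.  Passing recovery tests therefore shows the machinery is
correct on instances satisfying the model's assumptions, not that the
thresholds used to build S from real BLAST output are well chosen.

## Numerical and design notes

- Spines are canonicalised (sorted gene tuples per slot) so they hash and
  compare identically regardless of construction order; partitions are
  reported in a canonical sort, making runs byte-reproducible.
- Genomes are processed in input order; no reordering heuristic.  Output
  invariance under genome permutation is tested instead.
- The worked-example instances are transcribed from their figure captions;
  the F1 correspondence set is the minimal clique-consistent relation
  producing exactly the caption's four spines.
- Projection spans are linear rank intervals even on circular genomes; the
  gap-gene count is span width + 1 minus the synton's gene count there.
- Degenerate inputs: an empty S yields an empty partition (exit 0); a
  single-vertex multigraph is one singleton synton; all-don't-care tuples
  are rejected by the quorum everywhere.

## Problem sizes in the test suite

Randomized verification runs on 2–4 genomes of 8–30 genes with S density
0.02–0.3, δ_gap 1–3, every admissible quorum and all three aggregators
(200 instances in the equivalence check, plus smaller property grids), and
planted-block recovery on 50 seeded clean instances — sizes at which the
brute-force oracle is exact and fast.  Larger, denser instances (typical of
ten close genomes at quorum 2) remain tractable for the engine but are
outside the oracle's reach by construction; the spine cap is the guard.

## Known limitations

- Gene orientation is ignored; inverted segments merge with their
  surroundings if proximity and correspondence allow.
- Intra-genome (self) syntenies are out of scope; S rejects intra-genome
  pairs.
- Partial gene-order conservation (bounding how far matched neighbourhoods
  may shuffle) is not implemented; gene order within a synton is free.
- The ⊑ filter is quadratic in the number of syntons.
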