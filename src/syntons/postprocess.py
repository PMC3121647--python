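"""Reporting filters and projections on a synton partition.

The ⊑ subsumption order removes redundancy: a synton whose genes all appear
inside the spines of a larger-cover synton adds nothing and is filtered out
when only maximal syntons are requested.  Projections map syntons back onto
the genomes (gene lists, rank spans, gap genes) and the per-pair statistic
records, for every S pair, the size of the largest synton containing both
genes — the quantity used to relate synteny block size to gene conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import InputError, LayeredDataGraph, CorrespondenceRelation
from .pnam import Partition, Synton
from .spines import Spine


def spine_subsumes(u: Spine, v: Spine) -> bool:
    """u ⊑ v: every non-don't-care gene of *u* is also a gene of *v*."""
    if u.n != v.n:
        raise InputError("spines of different arity cannot be compared")
    return u.cover() <= v.cover()


def synton_subsumes(C1: Synton, C2: Synton) -> bool:
    """C1 ⊑ C2: every spine of C1 is subsumed by some spine of C2."""
    v_spines = list(C2.spines)
    return all(
        any(spine_subsumes(u, v) for v in v_spines) for u in C1.spines
    )


def maximal_syntons(P: Partition) -> list[Synton]:
    """Syntons not strictly subsumed by another synton of the partition.

    A synton subsumed only by itself is kept; two distinct syntons that
    subsume each other are both kept (only *strict* subsumption removes).
    """
    syntons = list(P)
    keep: list[Synton] = []
    for c1 in syntons:
        strictly_subsumed = any(
            c1 is not c2
            and synton_subsumes(c1, c2)
            and not synton_subsumes(c2, c1)
            for c2 in syntons
        )
        if not strictly_subsumed:
            keep.append(c1)
    return keep


def filter_min_size(P: Partition, m: int) -> list[Synton]:
    """Syntons with at least *m* spines."""
    if m < 1:
        raise InputError(f"min size must be >= 1, got {m}")
    return [c for c in P if c.size >= m]


@dataclass(frozen=True)
class ProjectionRecord:
    """One synton projected onto one covered genome."""

    synton_id: int
    genome_index: int
    genes: tuple[str, ...]  # sorted by rank
    span: tuple[int, int]  # min/max rank, inclusive
    gap_genes: int  # genes inside the span not in the synton

    @property
    def span_width(self) -> int:
        return self.span[1] - self.span[0]


def project_synton(
    C: Synton, D: LayeredDataGraph, synton_id: int = 0
) -> list[ProjectionRecord]:
    """Project a synton back onto the layered data graph.

    One record per covered genome: the union of the synton's slot genes
    there, their rank span, and the count of gap genes (genes lying inside
    the span but belonging to no spine of this synton).  Spans are linear
    rank intervals even on circular genomes.
    """
    records: list[ProjectionRecord] = []
    for i in C.cover_layers:
        genome = D.genome(i)
        genes = sorted(
            {g for s in C.spines for g in (s.slot(i) or ())},
            key=genome.rank_of,
        )
        ranks = [genome.rank_of(g) for g in genes]
        lo, hi = min(ranks), max(ranks)
        gap = (hi - lo + 1) - len(genes)
        records.append(
            ProjectionRecord(synton_id, i, tuple(genes), (lo, hi), gap)
        )
    return records


@dataclass(frozen=True)
class PairSizeRecord:
    """Largest synton (in spines) containing both genes of one S pair."""

    gene_a: str
    gene_b: str
    max_size: int


def max_synton_size_per_pair(
    P: Partition,
    S: CorrespondenceRelation,
    include_zero: bool = False,
) -> list[PairSizeRecord]:
    """For every S pair, the spine count of the largest synton whose gene
    set contains both genes; pairs in no synton get ``max_size = 0`` and are
    excluded unless ``include_zero`` is set."""
    membership: dict[str, set[int]] = {}
    sizes: list[int] = []
    for idx, synton in enumerate(P):
        sizes.append(synton.size)
        for g in synton.genes():
            membership.setdefault(g, set()).add(idx)
    records: list[PairSizeRecord] = []
    for a, b in S:
        shared = membership.get(a, set()) & membership.get(b, set())
        max_size = max((sizes[i] for i in shared), default=0)
        if max_size == 0 and not include_zero:
            continue
        records.append(PairSizeRecord(a, b, max_size))
    return records
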