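"""Primary data model: gene-ordered genomes, the pairwise correspondence
relation S, and the layered data graph.

A genome is an ordered list of genes; two genes of the same genome are
*intra-layer neighbours* when their rank distance is at most ``delta_gap``
(wrap-around distance on circular genomes).  The correspondence relation S
is a symmetric, not necessarily transitive, many-to-many relation between
genes of *different* genomes — in practice thresholded sequence similarity
or an orthology assignment.  Together they form the layered data graph on
which everything else is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ResourceLimitError(RuntimeError):
    """A configurable combinatorial guard was exceeded."""


class InternalInvariantError(AssertionError):
    """A structural invariant the algorithms guarantee was violated (bug trap)."""


@dataclass(frozen=True, order=True)
class Gene:
    """A gene at a fixed position (rank) on one genome.

    Ranks are 1-based and dense within a genome (1..L).  ``gene_id`` must be
    globally unique so that pair tables can reference genes without naming
    the genome.
    """

    genome_index: int
    gene_id: str
    rank: int


class Genome:
    """Rank-ordered sequence of genes on one (linear or circular) replicon."""

    def __init__(
        self,
        index: int,
        genes: Sequence[Gene],
        *,
        circular: bool = False,
        name: str | None = None,
    ) -> None:
        if index < 1:
            raise InputError(f"genome index must be >= 1, got {index}")
        if not genes:
            raise InputError(f"genome {index} has no genes")
        ordered = sorted(genes, key=lambda g: g.rank)
        ranks = [g.rank for g in ordered]
        if ranks != list(range(1, len(ordered) + 1)):
            raise InputError(
                f"genome {index}: ranks must be exactly 1..{len(ordered)} "
                f"with no duplicates (got {ranks[:10]}...)"
            )
        for g in ordered:
            if g.genome_index != index:
                raise InputError(
                    f"gene {g.gene_id!r} carries genome index {g.genome_index}, "
                    f"expected {index}"
                )
        self.index = index
        self.genes: tuple[Gene, ...] = tuple(ordered)
        self.circular = bool(circular)
        self.name = name if name is not None else str(index)
        self._rank_by_id: dict[str, int] = {}
        for g in ordered:
            if g.gene_id in self._rank_by_id:
                raise InputError(
                    f"genome {index}: duplicate gene id {g.gene_id!r}"
                )
            self._rank_by_id[g.gene_id] = g.rank

    @classmethod
    def from_ids(
        cls,
        index: int,
        gene_ids: Sequence[str],
        *,
        circular: bool = False,
        name: str | None = None,
    ) -> "Genome":
        """Build a genome from gene ids in chromosome order (ranks 1..L)."""
        genes = [Gene(index, gid, r) for r, gid in enumerate(gene_ids, start=1)]
        return cls(index, genes, circular=circular, name=name)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank_by_id

    def rank_of(self, gene_id: str) -> int:
        try:
            return self._rank_by_id[gene_id]
        except KeyError:
            raise InputError(
                f"gene {gene_id!r} not on genome {self.index}"
            ) from None

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def rank_distance(self, rank_a: int, rank_b: int) -> int:
        """Gene-order distance between two ranks; wrap-around when circular."""
        d = abs(rank_a - rank_b)
        if self.circular:
            d = min(d, len(self) - d)
        return d

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        shape = "circular" if self.circular else "linear"
        return f"<Genome {self.name} ({shape}, {len(self)} genes)>"


def interval_edge(u: Gene, v: Gene, delta_gap: int, genome: Genome) -> bool:
    """True iff *u* and *v* are intra-layer neighbours on ``genome``.

    The rule is ``d(u, v) <= delta_gap`` where d is the absolute rank
    difference on linear genomes and the wrap-around distance
    ``min(|Δ|, L − |Δ|)`` on circular ones.  A gene is its own neighbour
    (distance 0).  ``delta_gap = g`` therefore allows up to ``g − 1``
    intervening genes.
    """
    if delta_gap < 1:
        raise InputError(f"delta_gap must be >= 1, got {delta_gap}")
    if u.genome_index != v.genome_index or u.genome_index != genome.index:
        raise InputError(
            f"interval_edge requires genes of genome {genome.index}; got "
            f"{u.gene_id!r} (genome {u.genome_index}) and "
            f"{v.gene_id!r} (genome {v.genome_index})"
        )
    return genome.rank_distance(u.rank, v.rank) <= delta_gap


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class CorrespondenceRelation:
    """Symmetric inter-genome gene relation S (many-to-many, not transitive).

    Stored as unordered gene-id pairs plus an adjacency index.  Self pairs
    are rejected here; intra-genome pairs are rejected when the relation is
    attached to genomes in :func:`build_layered_graph`.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[tuple[str, str]] = set()
        self._adj: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise InputError(f"self pair {a!r}-{b!r} is not allowed in S")
        pair = _canonical_pair(a, b)
        if pair in self._pairs:
            return
        self._pairs.add(pair)
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def neighbours(self, gene_id: str) -> frozenset[str]:
        return frozenset(self._adj.get(gene_id, ()))

    def related(self, a: str, b: str) -> bool:
        return _canonical_pair(a, b) in self._pairs

    def genes(self) -> frozenset[str]:
        return frozenset(self._adj)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canonical_pair(*pair) in self._pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._pairs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CorrespondenceRelation with {len(self)} pairs>"


class LayeredDataGraph:
    """The n genomes plus S plus the gap parameter.

    Intra-layer edges are implicit (the interval rule); they are only
    materialised on request via :meth:`intra_layer_edges`.
    """

    def __init__(
        self,
        genomes: Sequence[Genome],
        S: CorrespondenceRelation,
        delta_gap: int,
    ) -> None:
        if len(genomes) < 2:
            raise InputError("a layered data graph needs at least 2 genomes")
        if delta_gap < 1:
            raise InputError(f"delta_gap must be >= 1, got {delta_gap}")
        indices = [g.index for g in genomes]
        if indices != list(range(1, len(genomes) + 1)):
            raise InputError(
                f"genome indices must be exactly 1..{len(genomes)}, got {indices}"
            )
        self.genomes: tuple[Genome, ...] = tuple(genomes)
        self.S = S
        self.delta_gap = delta_gap
        self._gene_by_id: dict[str, Gene] = {}
        for genome in genomes:
            for gene in genome:
                if gene.gene_id in self._gene_by_id:
                    raise InputError(
                        f"gene id {gene.gene_id!r} appears on more than one genome"
                    )
                self._gene_by_id[gene.gene_id] = gene
        for a, b in S.pairs:
            ga = self._resolve(a)
            gb = self._resolve(b)
            if ga.genome_index == gb.genome_index:
                raise InputError(
                    f"pair {a!r}-{b!r} is intra-genome (genome {ga.genome_index})"
                )

    def _resolve(self, gene_id: str) -> Gene:
        try:
            return self._gene_by_id[gene_id]
        except KeyError:
            raise InputError(f"unknown gene id {gene_id!r} in pair table") from None

    @property
    def n(self) -> int:
        return len(self.genomes)

    def genome(self, index: int) -> Genome:
        """Genome by 1-based index."""
        return self.genomes[index - 1]

    def gene(self, gene_id: str) -> Gene:
        return self._resolve(gene_id)

    def rank(self, gene_id: str) -> int:
        return self._resolve(gene_id).rank

    def genome_of(self, gene_id: str) -> int:
        return self._resolve(gene_id).genome_index

    def interval_edge(self, id_a: str, id_b: str) -> bool:
        """Intra-layer neighbourhood test by gene id, at this graph's δ_gap."""
        a = self._resolve(id_a)
        b = self._resolve(id_b)
        if a.genome_index != b.genome_index:
            raise InputError(
                f"{id_a!r} and {id_b!r} are on different genomes"
            )
        return interval_edge(a, b, self.delta_gap, self.genome(a.genome_index))

    def intra_layer_edges(self, index: int) -> list[tuple[str, str]]:
        """Materialise E_i for genome ``index`` (distinct gene pairs only)."""
        genome = self.genome(index)
        ids = genome.gene_ids()
        L = len(ids)
        edges: list[tuple[str, str]] = []
        for i in range(L):
            for j in range(i + 1, L):
                if genome.rank_distance(i + 1, j + 1) <= self.delta_gap:
                    edges.append(_canonical_pair(ids[i], ids[j]))
        return sorted(set(edges))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LayeredDataGraph n={self.n}, |S|={len(self.S)}, "
            f"delta_gap={self.delta_gap}>"
        )


def build_layered_graph(
    genomes: Sequence[Genome],
    pairs: CorrespondenceRelation | Iterable[tuple[str, str]],
    delta_gap: int,
) -> LayeredDataGraph:
    """Validate and assemble a layered data graph.

    Rejects unknown gene ids, intra-genome pairs and duplicate ranks;
    symmetric duplicates in ``pairs`` are stored once.
    """
    if not isinstance(pairs, CorrespondenceRelation):
        pairs = CorrespondenceRelation(pairs)
    return LayeredDataGraph(genomes, pairs, delta_gap)


@dataclass(frozen=True)
class BlastHit:
    """One row of an all-against-all protein comparison, plus protein lengths."""

    query_id: str
    subject_id: str
    p_value: float
    percent_identity: float
    alignment_length: int
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if self.query_length < 1 or self.subject_length < 1:
            raise InputError("protein lengths must be >= 1")
        if self.alignment_length < 1:
            raise InputError("alignment length must be >= 1")

    @property
    def coverage(self) -> float:
        """Fraction of the smaller protein covered by the alignment."""
        return self.alignment_length / min(self.query_length, self.subject_length)


def filter_blast_pairs(
    hits: Iterable[BlastHit],
    max_p: float = 1e-10,
    min_identity: float = 40.0,
    min_coverage: float = 0.80,
) -> CorrespondenceRelation:
    """Derive S from tabular hits by the standard three-threshold rule.

    A pair survives iff ``p_value <= max_p``, ``percent_identity >=
    min_identity`` and the alignment covers at least ``min_coverage`` of the
    smaller protein.  The result is symmetrised (query/subject order is
    irrelevant) and self hits are dropped.
    """
    if not (0.0 < min_coverage <= 1.0):
        raise InputError(f"min_coverage must be in (0, 1], got {min_coverage}")
    rel = CorrespondenceRelation()
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if hit.p_value > max_p:
            continue
        if hit.percent_identity < min_identity:
            continue
        if hit.coverage < min_coverage:
            continue
        rel.add(hit.query_id, hit.subject_id)
    return rel
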