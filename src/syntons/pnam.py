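"""Explicit (P)NAM construction and the definition-driven synton partition.

This is the brute-force oracle: materialise the multigraph's vertices and
colour edges, then compute syntons directly from their definition — groups
of spines with a uniform covered-layer set I (|I| >= q), connected on every
colour i in I, and maximal.  The production engine in
:mod:`syntons.engine` must return exactly the same partition; that
equivalence is the central correctness check of the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .model import (
    InputError,
    InternalInvariantError,
    LayeredDataGraph,
    ResourceLimitError,
)
from .refine import refine_common_components
from .spines import DEFAULT_SPINE_CAP, Spine


def colour_edge(u: Spine, v: Spine, i: int, D: LayeredDataGraph) -> bool:
    """True iff spines *u* and *v* are joined by an edge of colour *i*.

    Both must cover layer *i* and some gene of u's slot i must lie within
    δ_gap of some gene of v's slot i.  A shared identical gene counts
    (distance 0), which is what lets two spines anchored on the same gene
    belong to one synton.
    """
    su = u.slot(i)
    sv = v.slot(i)
    if su is None or sv is None:
        return False
    genome = D.genome(i)
    for a in su:
        ra = genome.rank_of(a)
        for b in sv:
            if genome.rank_distance(ra, genome.rank_of(b)) <= D.delta_gap:
                return True
    return False


@dataclass(frozen=True)
class Synton:
    """A cover-uniform, per-colour-connected group of spines."""

    spines: frozenset[Spine]
    cover_layers: tuple[int, ...] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.spines:
            raise InputError("a synton cannot be empty")
        covers = {s.covered_layers for s in self.spines}
        if len(covers) != 1:
            raise InputError(f"mixed covers in one synton: {sorted(covers)}")
        object.__setattr__(self, "cover_layers", next(iter(covers)))

    @classmethod
    def of(cls, spines: Iterable[Spine]) -> "Synton":
        return cls(frozenset(spines), ())

    @property
    def size(self) -> int:
        """Number of spines (the synton's size)."""
        return len(self.spines)

    def genes(self) -> frozenset[str]:
        return frozenset(g for s in self.spines for g in s.cover())

    def sorted_spines(self) -> list[Spine]:
        return sorted(self.spines, key=lambda s: s.as_strings())

    def __repr__(self) -> str:
        inner = ", ".join(repr(s) for s in self.sorted_spines())
        return "{" + inner + "}"


@dataclass(frozen=True)
class Partition:
    """A set of syntons partitioning (a subset of) the PNAM vertices."""

    syntons: tuple[Synton, ...]

    @classmethod
    def of(cls, syntons: Iterable[Synton]) -> "Partition":
        ordered = sorted(
            syntons,
            key=lambda c: (c.cover_layers, [s.as_strings() for s in c.sorted_spines()]),
        )
        return cls(tuple(ordered))

    def __len__(self) -> int:
        return len(self.syntons)

    def __iter__(self):
        return iter(self.syntons)

    def spine_set(self) -> frozenset[Spine]:
        return frozenset(s for c in self.syntons for s in c.spines)

    def largest(self) -> Optional[Synton]:
        if not self.syntons:
            return None
        return max(self.syntons, key=lambda c: c.size)

    def as_synton_set(self) -> frozenset[frozenset[Spine]]:
        """Order-free canonical form, for equality between partitions."""
        return frozenset(c.spines for c in self.syntons)


def check_partition_property(
    partition: Partition, vertices: Iterable[Spine]
) -> None:
    """Assert syntons are pairwise disjoint and cover all ``vertices``."""
    seen: set[Spine] = set()
    for synton in partition:
        overlap = seen & synton.spines
        if overlap:
            raise InternalInvariantError(
                f"spines assigned to two syntons: {sorted(map(repr, overlap))[:3]}"
            )
        seen |= synton.spines
    expected = set(vertices)
    if seen != expected:
        missing = expected - seen
        extra = seen - expected
        raise InternalInvariantError(
            f"partition does not cover the PNAM vertices "
            f"(missing {len(missing)}, extra {len(extra)})"
        )


class PNAM:
    """Materialised partial network alignment multigraph."""

    def __init__(
        self,
        vertices: Iterable[Spine],
        edges: Sequence[set[frozenset[Spine]]],
    ) -> None:
        self.vertices: frozenset[Spine] = frozenset(vertices)
        self.edges: tuple[set[frozenset[Spine]], ...] = tuple(edges)
        for i, colour in enumerate(self.edges, start=1):
            for pair in colour:
                if len(pair) != 2:
                    raise InputError("colour edges must join two distinct spines")
                for s in pair:
                    if s not in self.vertices:
                        raise InputError(
                            f"edge endpoint {s!r} is not a PNAM vertex"
                        )
                    if s.slot(i) is None:
                        raise InputError(
                            f"colour-{i} edge touches a spine not covered at {i}"
                        )

    @property
    def n(self) -> int:
        return len(self.edges)

    def edge_counts(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.edges)

    def colour_graph(self, i: int, within: Iterable[Spine]) -> nx.Graph:
        """The colour-i subgraph restricted to ``within``."""
        nodes = set(within)
        g = nx.Graph()
        g.add_nodes_from(n for n in nodes if n.slot(i) is not None)
        for pair in self.edges[i - 1]:
            a, b = tuple(pair)
            if a in nodes and b in nodes:
                g.add_edge(a, b)
        return g

    def to_json(self) -> str:
        """Debug export: vertices plus per-colour edge lists."""
        verts = sorted(self.vertices, key=lambda s: s.as_strings())
        index = {s: i for i, s in enumerate(verts)}
        payload = {
            "schema": "pnam/1",
            "vertices": [list(s.as_strings()) for s in verts],
            "edges": {
                str(i): sorted(
                    sorted([index[a], index[b]])
                    for a, b in (tuple(p) for p in colour)
                )
                for i, colour in enumerate(self.edges, start=1)
            },
        }
        return json.dumps(payload, indent=1)


def build_pnam(
    spines: Iterable[Spine],
    D: LayeredDataGraph,
    edge_cap: int = DEFAULT_SPINE_CAP,
) -> PNAM:
    """Materialise all colour edges between the given spines.

    Colour-i candidates are found by sorting slot-i rank occupancies, so
    only pairs within δ_gap are examined; each candidate pair is confirmed
    with :func:`colour_edge`.
    """
    verts = sorted(set(spines), key=lambda s: s.as_strings())
    edges: list[set[frozenset[Spine]]] = [set() for _ in range(D.n)]
    for i in range(1, D.n + 1):
        genome = D.genome(i)
        covered = [s for s in verts if s.slot(i) is not None]
        entries: list[tuple[int, int]] = []  # (rank, vertex position)
        for pos, s in enumerate(covered):
            for gid in s.slot(i):
                entries.append((genome.rank_of(gid), pos))
        entries.sort()
        colour = edges[i - 1]
        L = len(genome)
        for a_idx, (ra, pa) in enumerate(entries):
            for rb, pb in entries[a_idx + 1:]:
                if rb - ra > D.delta_gap:
                    break
                if pa != pb:
                    colour.add(frozenset((covered[pa], covered[pb])))
        if genome.circular and entries:
            # wrap-around candidates: tail entries vs head entries
            head = [e for e in entries if e[0] - entries[0][0] <= D.delta_gap]
            tail = [e for e in entries if entries[-1][0] - e[0] <= D.delta_gap]
            for rb, pb in tail:
                for ra, pa in head:
                    if pa != pb and (ra + L) - rb <= D.delta_gap:
                        colour.add(frozenset((covered[pa], covered[pb])))
        if len(colour) > edge_cap:
            raise ResourceLimitError(
                f"edge cap {edge_cap} exceeded while materialising colour {i}"
            )
    return PNAM(verts, edges)


def oracle_partition(
    pnam: PNAM,
    q: int,
    colour_order: Optional[Sequence[int]] = None,
) -> Partition:
    """Definition-driven synton partition of a materialised PNAM.

    Vertices are grouped by covered-layer signature I; each group is then
    refined to the coarsest partition whose parts are connected on every
    colour i in I (fixpoint splitting by one colour's connected components
    at a time).  ``colour_order`` only reorders the refinement passes — the
    result is provably order-independent, which the test suite exercises.
    """
    if q < 2:
        raise InputError(f"quorum must be >= 2, got {q}")
    groups: dict[tuple[int, ...], list[Spine]] = {}
    for v in pnam.vertices:
        if len(v.covered_layers) < q:
            raise InputError(f"vertex {v!r} violates the quorum {q}")
        groups.setdefault(v.covered_layers, []).append(v)
    syntons: list[Synton] = []
    for cover_layers, members in groups.items():
        order = list(colour_order) if colour_order is not None else list(cover_layers)
        order = [i for i in order if i in cover_layers]
        parts: list[list[Spine]] = [members]
        changed = True
        while changed:
            changed = False
            for i in order:
                nxt: list[list[Spine]] = []
                for part in parts:
                    if len(part) <= 1:
                        nxt.append(part)
                        continue
                    comps = [
                        list(c)
                        for c in nx.connected_components(
                            pnam.colour_graph(i, part)
                        )
                    ]
                    if len(comps) > 1:
                        changed = True
                    nxt.extend(comps)
                parts = nxt
        syntons.extend(Synton.of(p) for p in parts)
    partition = Partition.of(syntons)
    check_partition_property(partition, pnam.vertices)
    return partition


def refine_spines(
    spines: Iterable[Spine], D: LayeredDataGraph, q: int
) -> Partition:
    """Synton partition straight from a spine set, without materialised edges.

    Same cover-grouping as :func:`oracle_partition`, but colour components
    are computed by rank-proximity runs (:mod:`syntons.refine`).  Scales to
    PNAMs whose explicit edge sets would be quadratically large.
    """
    if q < 2:
        raise InputError(f"quorum must be >= 2, got {q}")
    spine_list = list(set(spines))
    groups: dict[tuple[int, ...], list[Spine]] = {}
    for v in spine_list:
        if len(v.covered_layers) < q:
            raise InputError(f"spine {v!r} violates the quorum {q}")
        groups.setdefault(v.covered_layers, []).append(v)
    syntons: list[Synton] = []
    for cover_layers, members in groups.items():
        genome_ranks = {
            i: {g.gene_id: g.rank for g in D.genome(i)} for i in cover_layers
        }

        def ranks_on(spine: Spine, layer: int) -> list[int]:
            table = genome_ranks[layer]
            return [table[g] for g in spine.slot(layer)]

        parts = refine_common_components(
            members, cover_layers, ranks_on, D.genome, D.delta_gap
        )
        syntons.extend(Synton.of(p) for p in parts)
    partition = Partition.of(syntons)
    check_partition_property(partition, spine_list)
    return partition


def is_synton(spines: set[Spine], pnam: PNAM, q: int) -> bool:
    """Check the three clauses of the synton definition on a candidate set.

    Uniform cover I with |I| >= q; connectivity on every colour i in I
    *within the set*; and maximality — no vertex of equal cover can be
    added while keeping the set connected on all colours of I.
    """
    if not spines or not spines <= pnam.vertices:
        return False
    covers = {s.covered_layers for s in spines}
    if len(covers) != 1:
        return False
    cover_layers = next(iter(covers))
    if len(cover_layers) < q:
        return False

    def connected_on_all(vertex_set: set[Spine]) -> bool:
        for i in cover_layers:
            g = pnam.colour_graph(i, vertex_set)
            if g.number_of_nodes() != len(vertex_set) or not nx.is_connected(g):
                return False
        return True

    if not connected_on_all(spines):
        return False
    for v in pnam.vertices - spines:
        if v.covered_layers == cover_layers and connected_on_all(spines | {v}):
            return False
    return True
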