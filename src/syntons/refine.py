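"""Per-colour connectivity refinement without materialised edges.

Two spines are colour-i adjacent when some gene in one's slot i lies within
δ_gap of some gene in the other's (a shared identical gene counts, distance
0).  On one genome this is a proximity relation on rank positions, so the
connected components of a spine set are exactly the maximal runs of its
sorted rank occupancies with consecutive gaps <= δ_gap (plus the wrap-around
join on circular genomes).  This gives near-linear colour components and is
the workhorse behind both the engine's finalisation and the scalable oracle
path; the definitional edge-based refinement in :mod:`syntons.pnam`
cross-checks it on small instances.
"""

from __future__ import annotations

from typing import Callable, Hashable, Iterable, Sequence, TypeVar

from .model import Genome

T = TypeVar("T", bound=Hashable)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def proximity_components(
    members: Sequence[T],
    ranks_of: Callable[[T], Iterable[int]],
    genome: Genome,
    delta_gap: int,
) -> list[list[T]]:
    """Group ``members`` into components of the rank-proximity relation.

    ``ranks_of`` yields the rank positions a member occupies on ``genome``;
    members whose occupancies come within ``delta_gap`` of each other
    (directly or through other members) share a component.
    """
    if not members:
        return []
    uf = _UnionFind(len(members))
    entries: list[tuple[int, int]] = []
    for idx, m in enumerate(members):
        for r in ranks_of(m):
            entries.append((r, idx))
    entries.sort()
    for (r_prev, i_prev), (r_next, i_next) in zip(entries, entries[1:]):
        if r_next - r_prev <= delta_gap:
            uf.union(i_prev, i_next)
    if genome.circular and len(entries) > 1:
        r_first, i_first = entries[0]
        r_last, i_last = entries[-1]
        if (r_first + len(genome)) - r_last <= delta_gap:
            uf.union(i_last, i_first)
    groups: dict[int, list[T]] = {}
    for idx, m in enumerate(members):
        groups.setdefault(uf.find(idx), []).append(m)
    return list(groups.values())


def refine_common_components(
    members: Sequence[T],
    layers: Sequence[int],
    ranks_on: Callable[[T, int], Iterable[int]],
    genome_of_layer: Callable[[int], Genome],
    delta_gap: int,
) -> list[list[T]]:
    """Coarsest partition of ``members`` into parts connected on every layer.

    Fixpoint refinement: repeatedly replace each part by its colour-i
    components (within the part), cycling the layers until a full pass
    splits nothing.  Every member must occupy every listed layer (uniform
    cover), so the result is the common-connected-component partition.
    """
    parts: list[list[T]] = [list(members)]
    changed = True
    while changed:
        changed = False
        for layer in layers:
            genome = genome_of_layer(layer)
            next_parts: list[list[T]] = []
            for part in parts:
                if len(part) <= 1:
                    next_parts.append(part)
                    continue
                comps = proximity_components(
                    part, lambda m: ranks_on(m, layer), genome, delta_gap
                )
                if len(comps) > 1:
                    changed = True
                next_parts.extend(comps)
            parts = next_parts
    return parts
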