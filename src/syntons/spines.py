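"""n-way partial gene correspondence: spines, quorum, aggregation modes.

A *spine* assigns to each of the n genomes either a non-empty gene set or a
don't-care mark.  The quorum q bounds the don't-care slots (at most n − q),
so a spine covers at least q genomes.  How genes tie together into one
spine is decided by the aggregator applied to the pairwise relation S:

* ``clique`` — all covered genes pairwise S-related (one gene per slot);
* ``connected_component`` — one spine per connected component of S
  (a slot may then hold several genes of the same genome);
* ``quasi_clique`` — one gene per slot, each covered gene S-related to at
  least γ·(k−1) of the other k−1 covered genes.

Explicit enumeration here is the definitional route used by the oracle; the
production engine builds the same spines on the fly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .model import (
    CorrespondenceRelation,
    InputError,
    LayeredDataGraph,
    ResourceLimitError,
)

#: textual rendering of the don't-care mark
DONT_CARE = "*"

CLIQUE = "clique"
CONNECTED_COMPONENT = "connected_component"
QUASI_CLIQUE = "quasi_clique"

#: default cap on the number of enumerated spines / live partial spines
DEFAULT_SPINE_CAP = 2_000_000


@dataclass(frozen=True)
class Aggregator:
    """Topology rule turning the pairwise relation S into spines."""

    mode: str
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in (CLIQUE, CONNECTED_COMPONENT, QUASI_CLIQUE):
            raise InputError(f"unknown aggregation mode {self.mode!r}")
        if self.mode == QUASI_CLIQUE:
            if self.gamma is None or not (0.0 < self.gamma <= 1.0):
                raise InputError(
                    f"quasi_clique needs gamma in (0, 1], got {self.gamma}"
                )
        elif self.gamma is not None:
            raise InputError(f"gamma is only meaningful for quasi_clique")

    @classmethod
    def clique(cls) -> "Aggregator":
        return cls(CLIQUE)

    @classmethod
    def connected_component(cls) -> "Aggregator":
        return cls(CONNECTED_COMPONENT)

    @classmethod
    def quasi_clique(cls, gamma: float) -> "Aggregator":
        return cls(QUASI_CLIQUE, gamma)


@dataclass(frozen=True)
class Spine:
    """One vertex of the (P)NAM: per-genome gene sets or don't-care marks.

    ``slots[i]`` is ``None`` (don't care) or a sorted tuple of gene ids of
    genome ``i + 1``.  The sorted-tuple canonical form makes spines hashable
    and equatable regardless of construction order.
    """

    slots: tuple[Optional[tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        canon: list[Optional[tuple[str, ...]]] = []
        for slot in self.slots:
            if slot is None:
                canon.append(None)
            else:
                genes = tuple(sorted(set(slot)))
                if not genes:
                    raise InputError("a covered slot must hold at least one gene")
                canon.append(genes)
        object.__setattr__(self, "slots", tuple(canon))

    @classmethod
    def of(cls, *entries: Optional[str | Iterable[str]]) -> "Spine":
        """Convenience constructor: ``Spine.of("a1", None, "a3")`` or with
        iterables per slot; the string ``"*"`` also means don't care."""
        slots: list[Optional[tuple[str, ...]]] = []
        for e in entries:
            if e is None or e == DONT_CARE:
                slots.append(None)
            elif isinstance(e, str):
                slots.append((e,))
            else:
                slots.append(tuple(e))
        return cls(tuple(slots))

    @property
    def n(self) -> int:
        return len(self.slots)

    @property
    def covered_layers(self) -> tuple[int, ...]:
        """1-based indices of the genomes this spine covers (the set I)."""
        return tuple(i + 1 for i, s in enumerate(self.slots) if s is not None)

    @property
    def dc_count(self) -> int:
        return sum(1 for s in self.slots if s is None)

    def slot(self, layer: int) -> Optional[tuple[str, ...]]:
        """Slot content for 1-based genome index ``layer``."""
        return self.slots[layer - 1]

    def cover(self) -> frozenset[str]:
        """All genes of the spine (the union of non-don't-care slots)."""
        return frozenset(
            g for s in self.slots if s is not None for g in s
        )

    def as_strings(self) -> tuple[str, ...]:
        """Render slots for reports: ``"*"`` or comma-joined gene ids."""
        return tuple(
            DONT_CARE if s is None else ",".join(s) for s in self.slots
        )

    def __repr__(self) -> str:
        return "(" + ", ".join(self.as_strings()) + ")"


def cover(v: Spine) -> frozenset[str]:
    """The set of genes of spine *v* that are not don't-care marks."""
    return v.cover()


def _quasi_degrees(genes: Iterable[str], S: CorrespondenceRelation) -> list[int]:
    gs = list(genes)
    return [sum(1 for o in gs if o != g and S.related(g, o)) for g in gs]


def is_valid_spine(
    candidate: Spine,
    S: CorrespondenceRelation,
    agg: Aggregator,
    q: int,
) -> bool:
    """Check the quorum and the aggregator's topology rule on a candidate.

    Don't-care slots are ignored by every rule; ``k`` below is the number of
    covered genes.
    """
    if q < 2:
        raise InputError(f"quorum must be >= 2, got {q}")
    if len(candidate.covered_layers) < q:
        return False
    genes = sorted(candidate.cover())
    if agg.mode == CLIQUE:
        return all(
            S.related(a, b) for a, b in itertools.combinations(genes, 2)
        )
    if agg.mode == QUASI_CLIQUE:
        k = len(genes)
        threshold = agg.gamma * (k - 1)
        return all(d >= threshold for d in _quasi_degrees(genes, S))
    # connected component: the covered genes form a connected subgraph of S
    if len(genes) == 1:
        return True
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for a, b in itertools.combinations(genes, 2):
        if S.related(a, b):
            graph.add_edge(a, b)
    return nx.is_connected(graph)


def _s_components(D: LayeredDataGraph) -> list[set[str]]:
    graph = nx.Graph()
    graph.add_nodes_from(D.S.genes())
    graph.add_edges_from(D.S.pairs)
    return [set(c) for c in nx.connected_components(graph)]


def _component_spines(D: LayeredDataGraph, q: int) -> set[Spine]:
    spines: set[Spine] = set()
    for comp in _s_components(D):
        slots: list[list[str]] = [[] for _ in range(D.n)]
        for gid in comp:
            slots[D.genome_of(gid) - 1].append(gid)
        covered = sum(1 for s in slots if s)
        if covered < q:
            continue
        spines.add(
            Spine(tuple(tuple(sorted(s)) if s else None for s in slots))
        )
    return spines


def _clique_spines(D: LayeredDataGraph, q: int, cap: int) -> set[Spine]:
    """All tuples (one gene per covered layer, >= q layers) forming S-cliques.

    Backtracking over layers 1..n, choosing a gene or don't care; genes must
    be S-related to every previously chosen gene.  Sub-cliques of larger
    cliques are distinct spines and are all produced.
    """
    n = D.n
    budget = n - q
    spines: set[Spine] = set()
    S = D.S

    def extend(layer: int, chosen: list[Optional[str]], dc_used: int) -> None:
        if layer > n:
            if n - dc_used >= q:
                spines.add(Spine.of(*chosen))
                if len(spines) > cap:
                    raise ResourceLimitError(
                        f"spine cap {cap} exceeded during enumeration; "
                        "raise the quorum or the cap"
                    )
            return
        prev = [g for g in chosen if g is not None]
        if prev:
            candidates: Iterable[str] = sorted(
                set.intersection(*(set(S.neighbours(g)) for g in prev))
                & set(D.genome(layer).gene_ids())
            )
        else:
            candidates = D.genome(layer).gene_ids()
        for gid in candidates:
            chosen.append(gid)
            extend(layer + 1, chosen, dc_used)
            chosen.pop()
        if dc_used < budget:
            chosen.append(None)
            extend(layer + 1, chosen, dc_used + 1)
            chosen.pop()

    extend(1, [], 0)
    return spines


def _quasi_spines_for_layers(
    D: LayeredDataGraph, layers: tuple[int, ...], gamma: float, cap: int
) -> Iterable[Spine]:
    """Tensor enumeration of quasi-clique tuples over one covered-layer set.

    Builds, by broadcasting, the within-tuple S-degree of every slot choice
    and keeps tuples whose minimum degree reaches γ·(k−1).  Independent of
    the depth-first engine by construction.
    """
    k = len(layers)
    ids = [D.genome(i).gene_ids() for i in layers]
    sizes = [len(x) for x in ids]
    # pairwise adjacency matrices between the chosen layers
    adj: dict[tuple[int, int], np.ndarray] = {}
    for a in range(k):
        for b in range(a + 1, k):
            m = np.zeros((sizes[a], sizes[b]), dtype=bool)
            for ia, ga in enumerate(ids[a]):
                nb = D.S.neighbours(ga)
                for ib, gb in enumerate(ids[b]):
                    if gb in nb:
                        m[ia, ib] = True
            adj[(a, b)] = m
    threshold = gamma * (k - 1)
    if k == 1:
        # a single covered gene has degree 0 >= gamma*0
        valid = np.ones(sizes[0], dtype=bool)
        degs = [valid]
    else:
        degs = []
        for a in range(k):
            deg = np.zeros(tuple(sizes), dtype=np.int16)
            for b in range(k):
                if a == b:
                    continue
                # adjacency is stored with axes in increasing layer-position
                # order, which is exactly the broadcast layout reshape needs
                lo, hi = min(a, b), max(a, b)
                m = adj[(lo, hi)]
                shape = [1] * k
                shape[lo] = sizes[lo]
                shape[hi] = sizes[hi]
                deg += m.reshape(shape).astype(np.int16)
            degs.append(deg)
        valid = np.ones(tuple(sizes), dtype=bool)
        for deg in degs:
            valid &= deg >= threshold
    hits = np.argwhere(valid)
    if len(hits) > cap:
        raise ResourceLimitError(
            f"spine cap {cap} exceeded during quasi-clique enumeration"
        )
    for idx in hits:
        slots: list[Optional[str]] = [None] * D.n
        for pos, layer in enumerate(layers):
            slots[layer - 1] = ids[pos][idx[pos]]
        yield Spine.of(*slots)


def enumerate_spines(
    D: LayeredDataGraph,
    agg: Aggregator,
    q: int,
    spine_cap: int = DEFAULT_SPINE_CAP,
) -> set[Spine]:
    """Explicitly enumerate all (P)NAM vertices (the oracle route).

    Clique and quasi-clique modes return *all* valid tuples with at least q
    covered layers — sub-cliques of a larger clique are distinct spines.
    Connected-component mode returns one spine per S-component spanning at
    least q genomes, each slot holding the component's genes on that genome.
    """
    if not (2 <= q <= D.n):
        raise InputError(f"quorum must be in [2, n={D.n}], got {q}")
    if agg.mode == CONNECTED_COMPONENT:
        spines = _component_spines(D, q)
        if len(spines) > spine_cap:
            raise ResourceLimitError(f"spine cap {spine_cap} exceeded")
        return spines
    if agg.mode == CLIQUE:
        return _clique_spines(D, q, spine_cap)
    spines: set[Spine] = set()
    for k in range(q, D.n + 1):
        for layers in itertools.combinations(range(1, D.n + 1), k):
            spines.update(
                _quasi_spines_for_layers(D, layers, agg.gamma, spine_cap)
            )
            if len(spines) > spine_cap:
                raise ResourceLimitError(f"spine cap {spine_cap} exceeded")
    return spines
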