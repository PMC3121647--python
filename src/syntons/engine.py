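"""Depth-first, on-the-fly synton computation with gene quorum.

Rather than materialising the full multigraph of spines, the engine adds
genomes one at a time in a depth-first search.  At each step the current
class of partial spines is SPLIT into per-colour connected components until
stable, then EXPANDed to the next genome: every member grows by each
*terminal* gene of that genome (a gene that can still complete the member
into a valid spine) and, while the don't-care budget n − q lasts, by a
don't-care mark.  Members that cannot grow are dead branches and are
dropped.  When a class is stable on all n colours its members are full
spines; finalisation filters out invalid tuples, splits by covered-layer
signature, re-refines, and deduplicates syntons produced in several
branches.  The result must equal the explicit oracle partition — a property
the test suite checks on hundreds of random instances.

Splitting with don't-care members follows the quorum rule: members with a
don't-care at the splitting colour are temporarily removed, components are
computed on the rest, and the removed members are added back to *every*
component.  This deliberately duplicates them across branches; correctness
is restored at finalisation by deduplication and re-refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    InputError,
    LayeredDataGraph,
    ResourceLimitError,
)
from .pnam import Partition, Synton, check_partition_property, refine_spines
from .postprocess import filter_min_size, maximal_syntons
from .refine import proximity_components
from .spines import (
    CLIQUE,
    CONNECTED_COMPONENT,
    DEFAULT_SPINE_CAP,
    QUASI_CLIQUE,
    Aggregator,
    Spine,
    is_valid_spine,
    _component_spines,
)

logger = logging.getLogger(__name__)

# a partial spine over layers 1..i: gene id per slot, or None for don't care
PartialSpine = tuple[Optional[str], ...]


@dataclass(frozen=True)
class EngineConfig:
    """Run parameters of the engine.

    ``min_size`` counts spines per synton; ``spine_cap`` bounds the number
    of live partial spines across the whole search (memory guard — the
    exact search can grow exponentially on many close genomes at low
    quorum).
    """

    quorum: int
    delta_gap: int = 1
    aggregator: Aggregator = field(default_factory=Aggregator.clique)
    min_size: int = 1
    maximal_only: bool = False
    spine_cap: int = DEFAULT_SPINE_CAP

    def __post_init__(self) -> None:
        if self.quorum < 2:
            raise InputError(f"quorum must be >= 2, got {self.quorum}")
        if self.delta_gap < 1:
            raise InputError(f"delta_gap must be >= 1, got {self.delta_gap}")
        if self.min_size < 1:
            raise InputError(f"min_size must be >= 1, got {self.min_size}")


@dataclass
class SearchClass:
    """A class of the depth-first search: partial spines over layers 1..i."""

    layer: int
    members: frozenset[PartialSpine]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("a search class cannot be empty")
        for m in self.members:
            if len(m) != self.layer:
                raise InputError(
                    f"member {m} has {len(m)} slots, expected {self.layer}"
                )

    @property
    def size(self) -> int:
        return len(self.members)


def _dc_count(member: PartialSpine) -> int:
    return sum(1 for s in member if s is None)


def initialize(D: LayeredDataGraph, cfg: EngineConfig) -> list[SearchClass]:
    """Initial classes: one per connected component of genome 1's interval
    graph (members are 1-tuples of its genes) plus, when q < n, a singleton
    class holding the don't-care 1-tuple."""
    _check_cfg(D, cfg)
    genome = D.genome(1)
    comps = proximity_components(
        [g.gene_id for g in genome],
        lambda gid: (genome.rank_of(gid),),
        genome,
        cfg.delta_gap,
    )
    classes = [
        SearchClass(1, frozenset((gid,) for gid in comp)) for comp in comps
    ]
    classes.sort(key=lambda c: min(c.members))
    if cfg.quorum < D.n:
        classes.append(SearchClass(1, frozenset({(None,)})))
    return classes


def _colour_components(
    members: Iterable[PartialSpine], j: int, D: LayeredDataGraph, delta_gap: int
) -> tuple[list[list[PartialSpine]], list[PartialSpine]]:
    """Components of colour j among members covered at j, plus the rest."""
    covered = []
    dc = []
    for m in members:
        (covered if m[j - 1] is not None else dc).append(m)
    genome = D.genome(j)
    comps = proximity_components(
        covered, lambda m: (genome.rank_of(m[j - 1]),), genome, delta_gap
    )
    return comps, dc


def split_class(C: SearchClass, D: LayeredDataGraph, cfg: EngineConfig) -> list[SearchClass]:
    """One SPLIT step over colours 1..layer.

    The first colour whose components separate the covered members wins:
    one class per component is returned, each augmented with *all* members
    that have a don't-care at that colour.  If no colour splits the class it
    is stable and returned unchanged (as a single-element list).
    """
    for j in range(1, C.layer + 1):
        comps, dc = _colour_components(C.members, j, D, cfg.delta_gap)
        if len(comps) > 1:
            return [
                SearchClass(C.layer, frozenset(comp) | frozenset(dc))
                for comp in comps
            ]
    return [C]


def _clique_terminals(
    member: PartialSpine, layer: int, D: LayeredDataGraph
) -> list[str]:
    covered = [g for g in member if g is not None]
    genome_ids = D.genome(layer).gene_ids()
    if not covered:
        return list(genome_ids)
    common = set(D.S.neighbours(covered[0]))
    for g in covered[1:]:
        common &= D.S.neighbours(g)
        if not common:
            return []
    return [gid for gid in genome_ids if gid in common]


def _quasi_feasible(
    genes: list[str], D: LayeredDataGraph, gamma: float, remaining: int
) -> bool:
    """Sound pruning bound for quasi-clique prefixes.

    A completed spine with covered size k needs every covered gene to have
    within-spine degree >= γ·(k−1).  With k' genes chosen and at most
    ``remaining`` layers left, a current degree d can grow to at most
    d + (k − k'), so the prefix is viable only if for every gene
    d >= γ·(k_max − 1) − remaining with k_max = k' + remaining.  At γ = 1
    this is exactly the clique-prefix rule.
    """
    k_prime = len(genes)
    threshold = gamma * (k_prime + remaining - 1) - remaining
    if threshold <= 0:
        return True
    for g in genes:
        nb = D.S.neighbours(g)
        d = sum(1 for o in genes if o != g and o in nb)
        if d < threshold:
            return False
    return True


def expand_class(
    C: SearchClass, D: LayeredDataGraph, cfg: EngineConfig
) -> Optional[SearchClass]:
    """EXPAND a stable class from layer i to layer i + 1.

    Each member grows by every terminal of the next genome and, if its
    don't-care budget allows, by a don't-care mark.  Members with no
    extension are dropped; a class with no surviving member is a dead
    branch (None).
    """
    if C.layer >= D.n:
        raise InputError("cannot expand a class already at the last layer")
    nxt = C.layer + 1
    budget = D.n - cfg.quorum
    remaining_after = D.n - nxt
    mode = cfg.aggregator.mode
    new_members: set[PartialSpine] = set()
    for m in C.members:
        if mode == CLIQUE:
            terminals = _clique_terminals(m, nxt, D)
        elif mode == QUASI_CLIQUE:
            covered = [g for g in m if g is not None]
            terminals = [
                gid
                for gid in D.genome(nxt).gene_ids()
                if _quasi_feasible(
                    covered + [gid], D, cfg.aggregator.gamma, remaining_after
                )
            ]
        else:  # pragma: no cover - CC mode never reaches incremental expand
            raise InputError(
                "connected-component aggregation does not use expand_class"
            )
        for t in terminals:
            new_members.add(m + (t,))
        if _dc_count(m) < budget:
            new_members.add(m + (None,))
    if not new_members:
        return None
    if len(new_members) > cfg.spine_cap:
        raise ResourceLimitError(
            f"live partial-spine cap {cfg.spine_cap} exceeded at layer {nxt}; "
            "raise the quorum or the cap"
        )
    return SearchClass(nxt, frozenset(new_members))


def finalize_classes(
    stable: Iterable[SearchClass], D: LayeredDataGraph, cfg: EngineConfig
) -> Partition:
    """Turn stable layer-n classes into the synton partition.

    Drops members that are not valid spines on the full tuple (quorum or
    aggregator violations — possible in quasi-clique mode where expansion
    only prunes with a necessary condition), splits by covered-layer
    signature, re-refines each group by per-colour connectivity, and
    deduplicates syntons discovered in several branches.  The partition
    property over all valid spines found is asserted.
    """
    all_spines: set[Spine] = set()
    syntons: dict[frozenset[Spine], Synton] = {}
    for C in stable:
        if C.layer != D.n:
            raise InputError("finalize_classes expects classes at the last layer")
        valid = []
        for m in C.members:
            spine = Spine.of(*m)
            if len(spine.covered_layers) < cfg.quorum:
                continue
            if cfg.aggregator.mode == QUASI_CLIQUE and not is_valid_spine(
                spine, D.S, cfg.aggregator, cfg.quorum
            ):
                continue
            valid.append(spine)
        if not valid:
            continue
        all_spines.update(valid)
        for synton in refine_spines(valid, D, cfg.quorum):
            syntons[synton.spines] = synton
    partition = Partition.of(syntons.values())
    check_partition_property(partition, all_spines)
    return partition


def _check_cfg(D: LayeredDataGraph, cfg: EngineConfig) -> None:
    if cfg.quorum > D.n:
        raise InputError(
            f"quorum {cfg.quorum} exceeds the number of genomes {D.n}"
        )


def partition_syntons(D: LayeredDataGraph, cfg: EngineConfig) -> Partition:
    """Compute the synton partition with the on-the-fly engine.

    Clique and quasi-clique modes run the split/expand depth-first search.
    Connected-component mode bypasses incremental expansion — its spines
    are whole S-components, precomputed — and goes straight to refinement.
    The raw partition is then passed through the maximal-synton filter
    (when ``cfg.maximal_only``) and the ``min_size`` filter.
    """
    _check_cfg(D, cfg)
    if cfg.aggregator.mode == CONNECTED_COMPONENT:
        spines = _component_spines(D, cfg.quorum)
        if len(spines) > cfg.spine_cap:
            raise ResourceLimitError(f"spine cap {cfg.spine_cap} exceeded")
        partition = refine_spines(spines, D, cfg.quorum) if spines else Partition.of([])
    else:
        stable_classes: list[SearchClass] = []
        stack: list[SearchClass] = initialize(D, cfg)
        live = sum(c.size for c in stack)
        while stack:
            C = stack.pop()
            live -= C.size
            parts = split_class(C, D, cfg)
            if len(parts) > 1:
                logger.debug(
                    "split layer=%d class of %d members into %d parts",
                    C.layer, C.size, len(parts),
                )
                stack.extend(parts)
                live += sum(p.size for p in parts)
            elif C.layer < D.n:
                NC = expand_class(C, D, cfg)
                if NC is not None:
                    logger.debug(
                        "expand layer=%d -> %d: %d -> %d members",
                        C.layer, NC.layer, C.size, NC.size,
                    )
                    stack.append(NC)
                    live += NC.size
            else:
                stable_classes.append(C)
            if live > cfg.spine_cap:
                raise ResourceLimitError(
                    f"live partial-spine cap {cfg.spine_cap} exceeded; "
                    "raise the quorum or the cap"
                )
        partition = finalize_classes(stable_classes, D, cfg)
    if cfg.maximal_only:
        partition = Partition.of(maximal_syntons(partition))
    return Partition.of(filter_min_size(partition, cfg.min_size))
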