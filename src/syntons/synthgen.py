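"""Deterministic worked-example fixtures and a seeded synthetic generator.

The two fixtures are tiny three-genome instances with hand-derivable synton
partitions; they double as documentation of the model.  The random
generator plants synteny blocks — groups of gene families laid out on a
subset of genomes, optionally permuted and interleaved with gap genes — in
otherwise unrelated background genomes, so recovery can be checked against
ground truth.  S edges connect same-family genes across genomes; a dropout
rate deletes some of them (making S non-transitive, as thresholded
similarity is in practice) and a paralog rate adds extra same-family copies
(making S many-to-many).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    CorrespondenceRelation,
    Genome,
    InputError,
    LayeredDataGraph,
    build_layered_graph,
)
from .pnam import Partition, Synton
from .spines import Spine

# -- transcribed worked-example fixtures ------------------------------------
#
# F1: three genomes, clique spines, no quorum slack (q = n = 3), strict
# adjacency.  Genome 1 carries a gap gene d1 between a1 and b1, so the
# single-spine synton {(a1,a2,a3)} stays separate from the three-spine
# synton {(b1,a2,a3), (b1,b2,b3), (c1,c2,c3)} (not blue-connected).  The
# S set is the minimal clique-consistent relation producing exactly those
# four spines.
#
# F2: three genomes, clique spines, quorum 2 (at most one don't care per
# spine); five spines, four syntons, of which two are maximal under ⊑.

_F1_GENOMES = {1: ["a1", "d1", "b1", "c1"], 2: ["a2", "b2", "c2"], 3: ["a3", "b3", "c3"]}
_F1_PAIRS = [
    ("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
    ("b1", "a2"), ("b1", "a3"),
    ("b1", "b2"), ("b1", "b3"), ("b2", "b3"),
    ("c1", "c2"), ("c1", "c3"), ("c2", "c3"),
]
_F2_GENOMES = {1: ["a1", "b1"], 2: ["a2", "b2"], 3: ["a3"]}
_F2_PAIRS = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"), ("b1", "b2")]


def fixture(name: str) -> tuple[LayeredDataGraph, Partition]:
    """Return a named fixture and its expected synton partition.

    ``F1`` is meant for clique spines with q = 3 (= n); ``F2`` for clique
    spines with q = 2.  Both use delta_gap = 1.
    """
    if name == "F1":
        genomes = [
            Genome.from_ids(i, ids) for i, ids in sorted(_F1_GENOMES.items())
        ]
        graph = build_layered_graph(genomes, _F1_PAIRS, delta_gap=1)
        expected = Partition.of(
            [
                Synton.of([Spine.of("a1", "a2", "a3")]),
                Synton.of(
                    [
                        Spine.of("b1", "a2", "a3"),
                        Spine.of("b1", "b2", "b3"),
                        Spine.of("c1", "c2", "c3"),
                    ]
                ),
            ]
        )
        return graph, expected
    if name == "F2":
        genomes = [
            Genome.from_ids(i, ids) for i, ids in sorted(_F2_GENOMES.items())
        ]
        graph = build_layered_graph(genomes, _F2_PAIRS, delta_gap=1)
        expected = Partition.of(
            [
                Synton.of([Spine.of("a1", "a2", "a3")]),
                Synton.of([Spine.of("a1", None, "a3")]),
                Synton.of([Spine.of(None, "a2", "a3")]),
                Synton.of(
                    [Spine.of("a1", "a2", None), Spine.of("b1", "b2", None)]
                ),
            ]
        )
        return graph, expected
    raise InputError(f"unknown fixture {name!r} (expected 'F1' or 'F2')")


# -- seeded random instances with planted blocks ----------------------------


@dataclass(frozen=True)
class PlantedBlock:
    """Ground truth for one planted synteny block."""

    families: tuple[str, ...]
    genomes: tuple[int, ...]
    #: per genome: gene ids of the block, in chromosome order
    placements: dict[int, tuple[str, ...]] = field(hash=False)

    def genes_on(self, genome_index: int) -> tuple[str, ...]:
        return self.placements[genome_index]

    def gene_set(self) -> frozenset[str]:
        return frozenset(g for p in self.placements.values() for g in p)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic instance.

    Defaults describe a small multi-genome comparison with a handful of
    conserved operon-sized blocks: modest genomes, blocks of five families
    shared by a subset of the genomes, free gene-order permutation, a light
    sprinkling of gap genes, and a clean (dropout- and paralog-free) S.
    """

    n_genomes: int = 3
    genome_length: int = 40
    n_blocks: int = 2
    block_length: int = 5
    subset_size: Optional[int] = None  # genomes per block; None = all
    permute: bool = True
    gap_rate: float = 0.1  # probability of a gap gene after each block gene
    dropout_rate: float = 0.0  # per S-edge deletion probability
    paralog_rate: float = 0.0  # per block gene, extra-copy probability
    delta_gap: int = 3  # neighbourhood radius of the generated instance
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.gap_rate, self.dropout_rate, self.paralog_rate):
            if not (0.0 <= rate <= 1.0):
                raise InputError(f"rates must be in [0, 1], got {rate}")
        if self.n_genomes < 2:
            raise InputError("need at least 2 genomes")
        if self.subset_size is not None and not (
            2 <= self.subset_size <= self.n_genomes
        ):
            raise InputError("subset_size must be in [2, n_genomes]")
        if self.block_length < 1 or self.n_blocks < 0:
            raise InputError("block_length >= 1 and n_blocks >= 0 required")
        if self.delta_gap < 1:
            raise InputError(f"delta_gap must be >= 1, got {self.delta_gap}")


def generate_instance(
    cfg: SynthConfig,
) -> tuple[LayeredDataGraph, list[PlantedBlock]]:
    """Generate a reproducible instance with planted, recoverable blocks.

    Background genes carry globally unique family labels (no S edges), so
    only planted-block genes can ever join a spine.  Each block occupies a
    contiguous stretch (plus optional interleaved gap genes) on each genome
    of its subset, in independently permuted order when ``permute`` is set.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genomes
    subset_size = cfg.subset_size if cfg.subset_size is not None else n

    # per-genome sequence of family labels; None is filled with background
    layouts: dict[int, list[Optional[str]]] = {i: [] for i in range(1, n + 1)}
    blocks_plan: list[tuple[tuple[str, ...], tuple[int, ...], dict[int, list[str]]]] = []
    for b in range(cfg.n_blocks):
        families = tuple(f"B{b}F{j}" for j in range(cfg.block_length))
        members = tuple(
            sorted(rng.choice(np.arange(1, n + 1), size=subset_size, replace=False))
        )
        orders: dict[int, list[str]] = {}
        for gi in members:
            order = list(families)
            if cfg.permute:
                order = [order[k] for k in rng.permutation(len(order))]
            orders[int(gi)] = order
        blocks_plan.append((families, tuple(int(g) for g in members), orders))

    # lay blocks out sequentially with >= 1 background gene between them
    for families, members, orders in blocks_plan:
        for gi in members:
            layout = layouts[gi]
            if layout:
                layout.append(None)  # separator background gene
            for fam in orders[gi]:
                layout.append(fam)
                if rng.random() < cfg.gap_rate:
                    layout.append(None)  # interleaved gap gene

    for gi in range(1, n + 1):
        if len(layouts[gi]) > cfg.genome_length:
            raise InputError(
                f"genome {gi} too short ({cfg.genome_length}) for the planted "
                f"blocks ({len(layouts[gi])} positions needed)"
            )

    genomes: list[Genome] = []
    gene_family: dict[str, str] = {}
    family_members: dict[str, dict[int, list[str]]] = {}
    background = 0
    for gi in range(1, n + 1):
        layout = list(layouts[gi])
        while len(layout) < cfg.genome_length:
            layout.append(None)
        ids: list[str] = []
        for pos, fam in enumerate(layout, start=1):
            gid = f"g{gi}_{pos}"
            ids.append(gid)
            if fam is None:
                background += 1
                gene_family[gid] = f"bg{background}"
            else:
                gene_family[gid] = fam
                family_members.setdefault(fam, {}).setdefault(gi, []).append(gid)
        genomes.append(Genome.from_ids(gi, ids, circular=cfg.circular))

    # paralogs: duplicate a block gene into a random background position
    if cfg.paralog_rate > 0:
        for fam, per_genome in sorted(family_members.items()):
            for gi, gids in sorted(per_genome.items()):
                for gid in list(gids):
                    if rng.random() < cfg.paralog_rate:
                        genome = genomes[gi - 1]
                        spare = [
                            g.gene_id
                            for g in genome
                            if gene_family[g.gene_id].startswith("bg")
                        ]
                        if spare:
                            pick = spare[int(rng.integers(len(spare)))]
                            gene_family[pick] = fam
                            per_genome.setdefault(gi, []).append(pick)

    pairs = CorrespondenceRelation()
    for fam, per_genome in sorted(family_members.items()):
        items = sorted(
            (gi, gid) for gi, gids in per_genome.items() for gid in gids
        )
        for idx_a in range(len(items)):
            for idx_b in range(idx_a + 1, len(items)):
                gi_a, ga = items[idx_a]
                gi_b, gb = items[idx_b]
                if gi_a == gi_b:
                    continue
                if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
                    continue
                pairs.add(ga, gb)

    graph = build_layered_graph(genomes, pairs, delta_gap=cfg.delta_gap)

    blocks: list[PlantedBlock] = []
    for families, members, orders in blocks_plan:
        placements: dict[int, tuple[str, ...]] = {}
        for gi in members:
            # the first recorded copy per family is the planted one
            # (paralog copies are appended afterwards)
            planted = {family_members[f][gi][0] for f in families}
            placements[gi] = tuple(
                g.gene_id for g in graph.genome(gi) if g.gene_id in planted
            )
        blocks.append(PlantedBlock(families, members, placements))
    return graph, blocks


def random_relation_instance(
    rng: np.random.Generator,
    n_genomes: int,
    genome_lengths: list[int],
    density: float,
    delta_gap: int = 1,
    circular: bool = False,
) -> LayeredDataGraph:
    """A genuinely unstructured instance: uniform random inter-genome S.

    Used for engine-versus-oracle equivalence checks, where no ground truth
    is needed — only that two independent routes agree.
    """
    genomes = [
        Genome.from_ids(
            gi,
            [f"g{gi}_{p}" for p in range(1, genome_lengths[gi - 1] + 1)],
            circular=circular,
        )
        for gi in range(1, n_genomes + 1)
    ]
    pairs = CorrespondenceRelation()
    for a in range(1, n_genomes + 1):
        for b in range(a + 1, n_genomes + 1):
            for ga in genomes[a - 1].gene_ids():
                for gb in genomes[b - 1].gene_ids():
                    if rng.random() < density:
                        pairs.add(ga, gb)
    return build_layered_graph(genomes, pairs, delta_gap)
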