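"""Explicit multigraph construction and the definition-driven partition."""

import itertools

import pytest

from syntons import (
    Aggregator,
    Partition,
    Spine,
    Synton,
    build_pnam,
    colour_edge,
    enumerate_spines,
    is_synton,
    oracle_partition,
    random_relation_instance,
    refine_spines,
)
from syntons.model import InputError


def _spines(D, q, agg=None):
    return enumerate_spines(D, agg or Aggregator.clique(), q)


class TestColourEdge:
    def test_shared_identical_gene_connects(self, f1):
        # both spines anchored on b1: distance 0 counts as neighbourhood
        D, _ = f1
        u = Spine.of("b1", "a2", "a3")
        v = Spine.of("b1", "b2", "b3")
        assert colour_edge(u, v, 1, D)

    def test_red_connection_through_adjacent_genes(self, f1):
        D, _ = f1
        u = Spine.of("a1", "a2", "a3")
        v = Spine.of("b1", "b2", "b3")
        assert colour_edge(u, v, 2, D)  # a2 and b2 adjacent

    def test_gap_gene_blocks_blue_connection(self, f1):
        D, _ = f1
        u = Spine.of("a1", "a2", "a3")
        v = Spine.of("b1", "b2", "b3")
        assert not colour_edge(u, v, 1, D)  # d1 separates a1 from b1

    def test_dont_care_slot_never_connects(self, f2):
        D, _ = f2
        u = Spine.of("a1", None, "a3")
        v = Spine.of("a1", "a2", None)
        assert not colour_edge(u, v, 2, D)
        assert colour_edge(u, v, 1, D)


class TestBuildPnam:
    def test_f2_colour3_edges_exactly_among_a3_spines(self, f2):
        D, _ = f2
        pnam = build_pnam(_spines(D, 2), D)
        a3_spines = {s for s in pnam.vertices if s.slot(3) is not None}
        assert len(a3_spines) == 3
        expected = {
            frozenset(p) for p in itertools.combinations(a3_spines, 2)
        }
        assert pnam.edges[2] == expected

    def test_single_spine_has_no_edges(self, f1):
        D, _ = f1
        pnam = build_pnam({Spine.of("a1", "a2", "a3")}, D)
        assert pnam.edge_counts() == (0, 0, 0)

    def test_f1_blue_edge_between_b_and_c_spines(self, f1):
        D, _ = f1
        pnam = build_pnam(_spines(D, 3), D)
        pair = frozenset({Spine.of("b1", "b2", "b3"), Spine.of("c1", "c2", "c3")})
        assert pair in pnam.edges[0]

    def test_edges_match_pairwise_colour_edge(self, rng):
        # bucketed construction against the naive all-pairs definition
        for _ in range(10):
            n = int(rng.integers(2, 4))
            lengths = [int(rng.integers(4, 10)) for _ in range(n)]
            circ = bool(rng.random() < 0.5)
            delta = int(rng.integers(1, 4))
            D = random_relation_instance(rng, n, lengths, 0.25, delta, circ)
            spines = _spines(D, 2)
            pnam = build_pnam(spines, D)
            for i in range(1, n + 1):
                naive = {
                    frozenset((u, v))
                    for u, v in itertools.combinations(spines, 2)
                    if colour_edge(u, v, i, D)
                }
                assert pnam.edges[i - 1] == naive


class TestOraclePartition:
    def test_f1_two_syntons_with_caption_membership(self, f1):
        D, expected = f1
        got = oracle_partition(build_pnam(_spines(D, 3), D), 3)
        assert got.as_synton_set() == expected.as_synton_set()

    def test_f2_four_syntons_with_caption_covers(self, f2):
        D, expected = f2
        got = oracle_partition(build_pnam(_spines(D, 2), D), 2)
        assert got.as_synton_set() == expected.as_synton_set()
        covers = sorted(c.cover_layers for c in got)
        assert covers == [(1, 2), (1, 2, 3), (1, 3), (2, 3)]
        assert max(c.size for c in got) == 2

    def test_single_vertex_pnam(self, f1):
        D, _ = f1
        pnam = build_pnam({Spine.of("a1", "a2", "a3")}, D)
        got = oracle_partition(pnam, 3)
        assert len(got) == 1 and got.syntons[0].size == 1

    def test_colour_order_independence(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 4))
            lengths = [int(rng.integers(4, 11)) for _ in range(n)]
            D = random_relation_instance(rng, n, lengths, 0.25,
                                         int(rng.integers(1, 3)))
            q = int(rng.integers(2, n + 1))
            spines = _spines(D, q)
            if not spines:
                continue
            pnam = build_pnam(spines, D)
            results = {
                oracle_partition(pnam, q, colour_order=perm).as_synton_set()
                for perm in itertools.permutations(range(1, n + 1))
            }
            assert len(results) == 1

    def test_rank_refinement_agrees_with_edge_refinement(self, rng):
        """The scalable edge-free refinement equals the materialised-edge
        oracle on random instances (all aggregators)."""
        for _ in range(40):
            n = int(rng.integers(2, 5))
            lengths = [int(rng.integers(4, 13)) for _ in range(n)]
            circ = bool(rng.random() < 0.3)
            D = random_relation_instance(rng, n, lengths, 0.2,
                                         int(rng.integers(1, 4)), circ)
            q = int(rng.integers(2, n + 1))
            agg = [Aggregator.clique(), Aggregator.connected_component(),
                   Aggregator.quasi_clique(0.5)][int(rng.integers(3))]
            spines = enumerate_spines(D, agg, q)
            if not spines:
                continue
            edge_based = oracle_partition(build_pnam(spines, D), q)
            rank_based = refine_spines(spines, D, q)
            assert edge_based.as_synton_set() == rank_based.as_synton_set()

    def test_delta_gap_monotone_coarsening(self, rng):
        """Raising delta_gap only merges syntons within a cover group."""
        for _ in range(15):
            n = int(rng.integers(2, 4))
            lengths = [int(rng.integers(6, 16)) for _ in range(n)]
            D1 = random_relation_instance(rng, n, lengths, 0.15, 1)
            q = 2
            spines = _spines(D1, q)
            if not spines:
                continue
            prev = refine_spines(spines, D1, q)
            for delta in (2, 3):
                import syntons.model as m

                D_next = m.build_layered_graph(D1.genomes, D1.S, delta)
                nxt = refine_spines(spines, D_next, q)
                parts_next = nxt.as_synton_set()
                for synton in prev:
                    assert any(synton.spines <= p for p in parts_next)
                prev = nxt

    def test_quorum_n_matches_no_quorum_nam(self, f1):
        # with q = n the PNAM is the plain NAM: no don't-care slots anywhere
        D, expected = f1
        spines = _spines(D, 3)
        assert all(s.dc_count == 0 for s in spines)
        got = oracle_partition(build_pnam(spines, D), 3)
        assert got.as_synton_set() == expected.as_synton_set()


class TestIsSynton:
    def test_caption_synton_accepted(self, f2):
        D, _ = f2
        pnam = build_pnam(_spines(D, 2), D)
        assert is_synton(
            {Spine.of("a1", "a2", None), Spine.of("b1", "b2", None)}, pnam, 2
        )

    def test_non_maximal_subset_rejected(self, f2):
        D, _ = f2
        pnam = build_pnam(_spines(D, 2), D)
        assert not is_synton({Spine.of("a1", "a2", None)}, pnam, 2)

    def test_mixed_covers_rejected(self, f2):
        D, _ = f2
        pnam = build_pnam(_spines(D, 2), D)
        assert not is_synton(
            {Spine.of("a1", "a2", "a3"), Spine.of("a1", "a2", None)}, pnam, 2
        )

    def test_every_oracle_part_is_a_synton(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 4))
            lengths = [int(rng.integers(4, 10)) for _ in range(n)]
            D = random_relation_instance(rng, n, lengths, 0.25)
            q = int(rng.integers(2, n + 1))
            spines = _spines(D, q)
            if not spines:
                continue
            pnam = build_pnam(spines, D)
            for synton in oracle_partition(pnam, q):
                assert is_synton(set(synton.spines), pnam, q)


class TestSyntonInvariants:
    def test_mixed_cover_synton_rejected_at_construction(self):
        with pytest.raises(InputError, match="mixed covers"):
            Synton.of([Spine.of("a1", "a2", "a3"), Spine.of("a1", "a2", None)])

    def test_empty_synton_rejected(self):
        with pytest.raises(InputError):
            Synton.of([])
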