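"""The on-the-fly split/expand engine against the explicit oracle."""

import json

import pytest

from syntons import (
    Aggregator,
    EngineConfig,
    Partition,
    Spine,
    build_layered_graph,
    enumerate_spines,
    partition_syntons,
    refine_spines,
)
from syntons.engine import (
    SearchClass,
    expand_class,
    finalize_classes,
    initialize,
    split_class,
)
from syntons.io import partition_payload
from syntons.model import Genome, InputError
from tests.conftest import random_setup


class TestInitialize:
    def test_f1_single_chain_class_without_dont_care(self, f1):
        # blue genome is one path a1-d1-b1-c1; q = n so no don't-care class
        D, _ = f1
        classes = initialize(D, EngineConfig(quorum=3))
        assert len(classes) == 1
        assert classes[0].members == {("a1",), ("d1",), ("b1",), ("c1",)}

    def test_f2_adds_dont_care_class_below_full_quorum(self, f2):
        D, _ = f2
        classes = initialize(D, EngineConfig(quorum=2))
        assert [c.members for c in classes] == [
            {("a1",), ("b1",)},
            {(None,)},
        ]

    def test_dense_linear_genome_is_one_component(self):
        # ranks are dense 1..L, so a linear genome's interval graph at any
        # delta_gap is a single chain: exactly one gene class (plus the
        # don't-care class below full quorum)
        g1 = Genome.from_ids(1, ["x", "f1", "f2", "f3", "y"])
        g2 = Genome.from_ids(2, ["z"])
        D = build_layered_graph([g1, g2], [], 1)
        classes = initialize(D, EngineConfig(quorum=2))
        assert len(classes) == 1
        assert len(classes[0].members) == 5


class TestSplit:
    def test_stable_class_returned_unchanged(self, f2):
        D, _ = f2
        C = SearchClass(2, frozenset({("a1", "a2"), ("b1", "b2"), (None, "a2")}))
        assert split_class(C, D, EngineConfig(quorum=2)) == [C]

    def test_disconnected_members_split_with_dont_care_duplication(self, f1):
        D, _ = f1
        # a1 (rank 1) and c1 (rank 4) are not delta_gap=1 neighbours
        C = SearchClass(1, frozenset({("a1",), ("c1",), (None,)}))
        parts = split_class(C, D, EngineConfig(quorum=2))
        assert len(parts) == 2
        # the don't-care member is duplicated into both branches
        assert {frozenset(p.members) for p in parts} == {
            frozenset({("a1",), (None,)}),
            frozenset({("c1",), (None,)}),
        }

    def test_singleton_class_is_stable(self, f1):
        D, _ = f1
        C = SearchClass(1, frozenset({("a1",)}))
        assert split_class(C, D, EngineConfig(quorum=3)) == [C]


class TestExpand:
    def test_f2_a_prefix_grows_by_terminal_and_dont_care(self, f2):
        D, _ = f2
        C = SearchClass(2, frozenset({("a1", "a2")}))
        NC = expand_class(C, D, EngineConfig(quorum=2))
        assert NC.members == {("a1", "a2", "a3"), ("a1", "a2", None)}

    def test_f2_b_prefix_has_no_layer3_terminal(self, f2):
        D, _ = f2
        C = SearchClass(2, frozenset({("b1", "b2")}))
        NC = expand_class(C, D, EngineConfig(quorum=2))
        assert NC.members == {("b1", "b2", None)}

    def test_budget_exhausted_member_without_terminal_dropped(self, f2):
        D, _ = f2
        # (b1, *) has used its single don't care (n-q = 1) and b1 has no
        # S partner on genome 3
        C = SearchClass(2, frozenset({("b1", None)}))
        assert expand_class(C, D, EngineConfig(quorum=2)) is None

    def test_expand_past_last_layer_rejected(self, f2):
        D, _ = f2
        C = SearchClass(3, frozenset({("a1", "a2", "a3")}))
        with pytest.raises(InputError):
            expand_class(C, D, EngineConfig(quorum=2))


class TestFullRuns:
    def test_f1_two_syntons(self, f1):
        D, expected = f1
        got = partition_syntons(D, EngineConfig(quorum=3))
        assert got.as_synton_set() == expected.as_synton_set()

    def test_f2_four_syntons(self, f2):
        D, expected = f2
        got = partition_syntons(D, EngineConfig(quorum=2))
        assert got.as_synton_set() == expected.as_synton_set()

    def test_f2_min_size_two_keeps_only_the_pair_synton(self, f2):
        D, _ = f2
        got = partition_syntons(D, EngineConfig(quorum=2, min_size=2))
        assert len(got) == 1 and got.syntons[0].size == 2

    def test_f2_maximal_only(self, f2):
        D, _ = f2
        got = partition_syntons(D, EngineConfig(quorum=2, maximal_only=True))
        assert len(got) == 2

    def test_engine_equals_oracle_on_random_instances(self, rng):
        for _ in range(60):
            D, cfg = random_setup(rng, max_genes=20)
            spines = enumerate_spines(D, cfg.aggregator, cfg.quorum)
            oracle = refine_spines(spines, D, cfg.quorum) if spines else Partition.of([])
            engine = partition_syntons(D, cfg)
            assert engine.as_synton_set() == oracle.as_synton_set()

    def test_genome_order_invariance(self, rng):
        for _ in range(12):
            D, cfg = random_setup(rng, max_genes=14)
            base = partition_syntons(D, cfg)
            perm = list(rng.permutation(D.n))  # new position -> old index
            genomes = [
                Genome.from_ids(
                    i + 1,
                    D.genomes[perm[i]].gene_ids(),
                    circular=D.genomes[perm[i]].circular,
                )
                for i in range(D.n)
            ]
            D2 = build_layered_graph(genomes, D.S, D.delta_gap)
            permuted = partition_syntons(D2, cfg)
            # map slots back to the original genome order
            inverse = {perm[i]: i for i in range(D.n)}
            restored = {
                frozenset(
                    Spine(tuple(s.slots[inverse[i]] for i in range(D.n)))
                    for s in synton
                )
                for synton in permuted.as_synton_set()
            }
            assert restored == set(base.as_synton_set())

    def test_quorum_monotonicity_of_spine_sets(self, rng):
        for _ in range(10):
            D, cfg = random_setup(rng, max_genes=14)
            if D.n < 3:
                continue
            higher = partition_syntons(
                D, EngineConfig(quorum=D.n, delta_gap=cfg.delta_gap,
                                aggregator=cfg.aggregator)
            )
            lower = partition_syntons(
                D, EngineConfig(quorum=2, delta_gap=cfg.delta_gap,
                                aggregator=cfg.aggregator)
            )
            assert lower.spine_set() >= higher.spine_set()

    def test_deterministic_canonical_output(self, rng):
        D, cfg = random_setup(rng, max_genes=15)
        p1 = partition_syntons(D, cfg)
        p2 = partition_syntons(D, cfg)
        s1 = json.dumps(partition_payload(p1, D), sort_keys=True)
        s2 = json.dumps(partition_payload(p2, D), sort_keys=True)
        assert s1 == s2

    def test_finalize_rejects_partial_layer_classes(self, f2):
        D, _ = f2
        with pytest.raises(InputError):
            finalize_classes(
                [SearchClass(2, frozenset({("a1", "a2")}))], D,
                EngineConfig(quorum=2),
            )
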