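import numpy as np
import pytest

from syntons import Aggregator, EngineConfig, fixture, random_relation_instance


@pytest.fixture()
def f1():
    """Three-genome worked example without quorum slack (q = n = 3)."""
    return fixture("F1")


@pytest.fixture()
def f2():
    """Three-genome worked example with quorum 2 (one don't care allowed)."""
    return fixture("F2")


def random_setup(rng, *, max_genes=30, min_genes=8):
    """One random engine/oracle comparison setup drawn from the standard
    study conditions: 2-4 genomes, 8-30 genes, S density 0.02-0.3,
    delta_gap 1-3, all aggregation modes, every admissible quorum."""
    n = int(rng.integers(2, 5))
    lengths = [int(rng.integers(min_genes, max_genes + 1)) for _ in range(n)]
    density = float(rng.uniform(0.02, 0.3))
    delta = int(rng.integers(1, 4))
    circular = bool(rng.random() < 0.25)
    D = random_relation_instance(rng, n, lengths, density, delta, circular)
    q = int(rng.integers(2, n + 1))
    mode = rng.choice(["clique", "cc", "quasi"])
    if mode == "clique":
        agg = Aggregator.clique()
    elif mode == "cc":
        agg = Aggregator.connected_component()
    else:
        agg = Aggregator.quasi_clique(float(rng.choice([0.5, 0.75, 1.0])))
    cfg = EngineConfig(quorum=q, delta_gap=delta, aggregator=agg)
    return D, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
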