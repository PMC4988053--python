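"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ddrnet import (Evidence, Network, NetworkMetadata, ScenarioParams,
                    simulate_scenario)


def make_network(edges, network_id="net", species=None, **meta):
    """Build a network from bare (tf, tg) pairs, one Database evidence each."""
    net = Network(NetworkMetadata(network_id=network_id, species=species, **meta))
    for tf, tg in edges:
        net.add_evidence(tf, tg, Evidence(kind="Database", source_network_id=network_id))
    return net


def random_network(rng: np.random.Generator, network_id: str,
                   n_genes: int = 12, density: float = 0.2) -> Network:
    genes = [f"g{i}" for i in range(n_genes)]
    edges = [(a, b) for a in genes for b in genes if rng.random() < density]
    return make_network(edges, network_id=network_id)


@pytest.fixture(scope="session")
def small_bundle():
    """A two-species scenario exercised by many integration tests."""
    return simulate_scenario(ScenarioParams(seed=11, n_species=2, n_genes=25, n_tfs=5))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
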