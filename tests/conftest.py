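"""Shared fixtures: tiny hand-built networks and a small simulated benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from mechnet import (
    CorrelationData,
    Interaction,
    InteractionNetwork,
    SimConfig,
    apply_90_10_rule,
    generate_network,
    simulate_correlations,
)


def make_network(edges, extra_nodes=()):
    """edges: iterable of (source, mechanism, target)."""
    return InteractionNetwork(
        [Interaction(f"{s}|{m}|{t}", s, t, m) for s, m, t in edges],
        extra_nodes=extra_nodes,
    )


@pytest.fixture
def chain_net():
    """a-b, b-c, c-d: the middle interaction has two neighbors."""
    return make_network([("a", "TR", "b"), ("b", "M", "c"), ("c", "B", "d")])


@pytest.fixture
def star_net():
    """Hub h with 4 spokes: every interaction neighbors the other three."""
    return make_network([("h", "B", f"s{i}") for i in range(4)])


@pytest.fixture
def disconnected_net():
    return make_network([("a", "B", "b"), ("c", "TR", "d")])


@pytest.fixture
def parallel_net():
    """Two parallel interactions with distinct mechanisms between a and b."""
    return make_network([("a", "B", "b"), ("a", "TR", "b"), ("b", "M", "c")])


@pytest.fixture(scope="session")
def small_benchmark():
    """A seeded 80-interaction benchmark: network, truth, one replicate."""
    config = SimConfig(n_interactions=80, n_pathway=32, seed=42)
    net, pathway = generate_network(config, seed=421)
    truth = apply_90_10_rule(net, pathway, config.class1, config.class2, seed=422)
    corr = simulate_correlations(truth, seed=423)
    return net, truth, corr


def corr_for(net, values=None, n=5, default=0.0):
    vals = {i: default for i in net.interactions}
    if values:
        vals.update(values)
    return CorrelationData(values=vals, n=n)
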