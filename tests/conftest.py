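"""Shared fixtures: small hand-built ARGs and model-exact random instances.

The hand-built graphs mirror the canonical teaching examples for this model:
a three-sample ARG with one recombination loop, and a minimal single-loop
graph where the sampled genome sits directly below the recombination node.
All fixtures are generated in memory; nothing is read from disk.
"""

import numpy as np
import pandas as pd
import pytest

import argspace as a


def build_arg(nodes, edges, locations, sequence_length=None):
    nodes = pd.DataFrame(nodes, columns=["id", "time", "is_sample"])
    edges = pd.DataFrame(edges, columns=["parent", "child", "left", "right"])
    loc = pd.DataFrame(locations)
    return a.SpatialARG.from_tables(nodes, edges, loc, sequence_length)


@pytest.fixture
def fig1_arg():
    """Three samples, one recombination node E(3) whose loop is
    E -> F(4) -> G(5) / E -> G, with C(2) joining at the root (6).

    Samples A(0), B(1) sit below the recombination node and have two paths
    each; the minimal path set has ns + 1 = 4 members.
    """
    return build_arg(
        nodes=[(0, 0, 1), (1, 0, 1), (2, 0, 1), (3, 1, 0), (4, 2, 0),
               (5, 3, 0), (6, 4, 0)],
        edges=[(3, 0, 0, 1), (3, 1, 0, 1), (4, 3, 0, 0.5), (5, 3, 0.5, 1),
               (5, 4, 0, 0.5), (6, 5, 0, 1), (6, 2, 0, 1)],
        locations={"node_id": [0, 1, 2], "x": [-0.5, 0.0, 0.5]},
    )


@pytest.fixture
def fig4_loop_arg():
    """One sampled genome E(0) directly below a single symmetric loop:
    parents F(1, t=1) and G(2, t=2), F a child of G.  The time from the loop
    top G to the recombination node is t = 2."""
    return build_arg(
        nodes=[(0, 0.0, 1), (1, 1.0, 0), (2, 2.0, 0)],
        edges=[(1, 0, 0, 0.5), (2, 0, 0.5, 1), (2, 1, 0, 0.5)],
        locations={"node_id": [0], "x": [0.3]},
    )


@pytest.fixture
def two_sample_tree():
    """Two samples at ±1 coalescing at a root at time T = 10."""
    return build_arg(
        nodes=[(0, 0, 1), (1, 0, 1), (2, 10.0, 0)],
        edges=[(2, 0, 0, 1), (2, 1, 0, 1)],
        locations={"node_id": [0, 1], "x": [-1.0, 1.0]},
    )


@pytest.fixture
def nested_recombination_arg():
    """One sample below two stacked recombination loops -> 2² = 4 full
    paths: each loop closes before the next one opens."""
    return build_arg(
        nodes=[(0, 0, 1), (1, 1.0, 0), (2, 2.0, 0), (3, 2.5, 0), (4, 3.0, 0),
               (5, 4.0, 0), (6, 4.5, 0), (7, 5.0, 0)],
        edges=[(1, 0, 0, 1),
               (2, 1, 0, 0.5), (3, 1, 0.5, 1),    # loop 1 opens at node 1
               (4, 2, 0, 0.5), (4, 3, 0.5, 1),    # closes at node 4 ...
               (5, 4, 0, 0.5), (6, 4, 0.5, 1),    # ... which opens loop 2
               (7, 5, 0, 0.5), (7, 6, 0.5, 1)],
        locations={"node_id": [0], "x": [0.0]},
    )


def make_located_arg(seed, ns=6, target_recombinations=2.0, sigma2=1.0,
                     ndim=1, chop_frac=None, mu=0.0, population_size=1e4):
    """Random model ARG with locations drawn exactly from the
    loop-conditioned Brownian model."""
    arg = a.simulate_model_arg(ns=ns, target_recombinations=target_recombinations,
                               seed=seed, ndim=ndim,
                               population_size=population_size)
    if chop_frac is not None:
        arg = a.chop_arg(arg, chop_frac * float(arg.nodes["time"].max()))
    nr = len(arg.roots)
    d = 2 if np.size(sigma2) == 4 else 1
    model = a.ModelSpec(mu=np.full((nr, d), mu), sigma2=sigma2)
    locs = a.simulate_locations(arg, model, "meeting", seed=seed + 10_000)
    return a.with_sample_locations(arg, locs), locs, model


@pytest.fixture
def located_arg_factory():
    return make_located_arg
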