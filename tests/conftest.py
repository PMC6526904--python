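"""Shared fixtures and tree generators for the test suite."""

import itertools

import numpy as np
import pytest

from clanshield import fixtures
from clanshield.treeio import SpeciesMap, UnrootedTree


def random_unrooted_tree(labels, rng, with_lengths=False):
    """Random binary unrooted tree by sequential leaf addition onto edges."""
    labels = list(labels)
    assert len(labels) >= 3
    adj = {0: {}, 1: {}}
    leaf = {0: labels[0], 1: labels[1]}
    ln = float(rng.uniform(0.5, 2.0)) if with_lengths else None
    adj[0][1] = ln
    adj[1][0] = ln
    nid = 2
    for lab in labels[2:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w, x = nid, nid + 1
        nid += 2
        old = adj[u].pop(v)
        adj[v].pop(u)
        if with_lengths:
            a = float(rng.uniform(0.2, 0.8)) * old
            b, c = old - a, float(rng.uniform(0.5, 2.0))
        else:
            a = b = c = None
        adj[w] = {u: a, v: b, x: c}
        adj[u][w] = a
        adj[v][w] = b
        adj[x] = {w: c}
        leaf[x] = lab
    edges = [(u, v, adj[u][v]) for u in adj for v in adj[u] if u < v]
    return UnrootedTree.from_edges(edges, leaf)


def pairwise_path_distances(tree, labels):
    return {
        frozenset((a, b)): tree.path_distance(a, b)
        for a, b in itertools.combinations(labels, 2)
    }


@pytest.fixture(scope="session")
def species_model():
    return fixtures.default_species_model()


@pytest.fixture(scope="session")
def species_map():
    return fixtures.default_species_map()


@pytest.fixture(scope="session")
def clan_set():
    return fixtures.default_clans()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_map():
    def make(labels):
        return SpeciesMap.identity(labels)

    return make
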