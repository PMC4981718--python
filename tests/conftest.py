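"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from viralnet.genomes import GenomeSet
from viralnet.network import BipartiteNetwork


def make_network(incidence: dict[str, list[str]]) -> BipartiteNetwork:
    """Build a BipartiteNetwork from genome -> families lists (no filtering)."""
    G = nx.Graph()
    genomes = list(incidence)
    fams: dict[str, None] = {}
    for g, fs in incidence.items():
        for f in fs:
            fams.setdefault(f)
    G.add_nodes_from(genomes, bipartite=0)
    G.add_nodes_from(fams, bipartite=1)
    for g, fs in incidence.items():
        for f in fs:
            G.add_edge(g, f)
    return BipartiteNetwork(G, genomes, list(fams))


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def brute_force_best_q(net: BipartiteNetwork) -> float:
    """Exact maximum Barber modularity by exhaustive enumeration.

    Enumerates all set partitions of the genome nodes; given a genome
    partition, Q decomposes additively over families, so each family is
    assigned to its best module (or left alone, contributing 0).
    """
    L = net.n_edges
    best = 0.0
    for part in set_partitions(list(net.genomes)):
        kg = [sum(net.graph.degree(g) for g in grp) for grp in part]
        groups = [set(grp) for grp in part]
        q = 0.0
        for f in net.families:
            kf = net.graph.degree(f)
            gains = [
                (sum(1 for g in net.graph[f] if g in grp) - kf * kg[i] / L) / L
                for i, grp in enumerate(groups)
            ]
            q += max(0.0, max(gains))
        best = max(best, q)
    return best


def random_bipartite(rng: np.random.Generator, max_side: int = 5) -> BipartiteNetwork:
    """A random bipartite graph with no isolated node on either side."""
    ng = int(rng.integers(2, max_side + 1))
    nf = int(rng.integers(2, max_side + 1))
    while True:
        M = rng.random((ng, nf)) < 0.5
        if M.sum(axis=1).min() > 0 and M.sum(axis=0).min() > 0:
            break
    return make_network(
        {f"g{i}": [f"f{j}" for j in range(nf) if M[i, j]] for i in range(ng)}
    )


@pytest.fixture
def two_k22_blocks() -> BipartiteNetwork:
    """Two disjoint complete-bipartite K_{2,2} blocks; optimal Q = 0.5."""
    return make_network(
        {
            "g1": ["f1", "f2"],
            "g2": ["f1", "f2"],
            "g3": ["f3", "f4"],
            "g4": ["f3", "f4"],
        }
    )


@pytest.fixture
def small_genomes() -> GenomeSet:
    return GenomeSet(
        {
            "gA": {"f1": 1, "f2": 1, "f3": 2},
            "gB": {"f1": 1, "f2": 1, "f3": 1},
            "gC": {"f4": 1, "f5": 1},
        }
    )
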