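"""Barber bipartite modularity, simulated annealing, replicate ensembles,
degree-preserving significance testing, and partition robustness.

The modularity of a partition that co-assigns genomes and families is

    Q = (1/L) * sum_{i in G} sum_{j in F} (a_ij - k_i k_j / L) delta(m_i, m_j)

with L the edge count, a_ij the adjacency indicator and k the degrees.
Optimisation uses Metropolis annealing over single-node label moves (to a
neighbouring module or a fresh one) with geometric cooling, followed by a
deterministic greedy polish and module-merge passes; the schedule is
exposed via :class:`AnnealSchedule`.  Significance is assessed against
degree-preserving randomisations (bipartite double-edge swaps), and module
robustness from co-assignment frequencies across replicate partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import _sa
from .network import BipartiteNetwork, FAMILY_CLASS, GENOME_CLASS


@dataclass
class Partition:
    """Node → module labels over both node classes, with its modularity Q."""

    labels: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def module_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.labels.items():
            out.setdefault(m, []).append(node)
        return out

    def genome_modules(self, network: BipartiteNetwork) -> dict[int, set[str]]:
        """Module → set of genome nodes (modules without genomes omitted)."""
        out: dict[int, set[str]] = {}
        for g in network.genomes:
            out.setdefault(self.labels[g], set()).add(g)
        return out


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule (geometric cooling).

    ``t0=None`` calibrates the initial temperature so that a typical
    Q-decreasing move is accepted with probability ~1/2.
    """

    t0: float | None = None
    cooling: float = 0.995
    moves_per_t_factor: int = 8  # moves per temperature = factor * n_nodes
    patience: int = 50  # cooling blocks without a new best before stopping
    t_min_factor: float = 1e-4  # stop when T < t_min_factor / L
    p_new_module: float = 0.05
    max_blocks: int = 3000
    merge_rounds: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must be in (0, 1) for a decreasing schedule")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")


def barber_modularity(network: BipartiteNetwork, labels: dict[str, int]) -> float:
    """Exact evaluation of Barber's bipartite modularity for ``labels``."""
    missing = [n for n in network.graph.nodes if n not in labels]
    if missing:
        raise ValueError(f"labels missing for node(s): {missing[:5]}")
    L = network.n_edges
    if L == 0:
        raise ValueError("network has no edges")
    kg: dict[int, float] = {}
    kf: dict[int, float] = {}
    e: dict[int, float] = {}
    for g in network.genomes:
        kg[labels[g]] = kg.get(labels[g], 0.0) + network.graph.degree(g)
    for f in network.families:
        kf[labels[f]] = kf.get(labels[f], 0.0) + network.graph.degree(f)
    for u, v in network.graph.edges():
        if labels[u] == labels[v]:
            e[labels[u]] = e.get(labels[u], 0.0) + 1.0
    q = 0.0
    for m in set(kg) | set(kf) | set(e):
        q += e.get(m, 0.0) / L - kg.get(m, 0.0) * kf.get(m, 0.0) / (L * L)
    return q


def _merge_pass(labels: np.ndarray, is_genome: np.ndarray, indptr, indices, k, L):
    """Greedily merge module pairs while any merge increases Q."""
    n = labels.shape[0]
    while True:
        uniq = np.unique(labels)
        relab = {m: i for i, m in enumerate(uniq)}
        lab = np.array([relab[m] for m in labels])
        nm = len(uniq)
        kg = np.zeros(nm)
        kf = np.zeros(nm)
        E = np.zeros((nm, nm))  # E[mg, mf]: edges between genome-side of mg, family-side of mf
        for u in range(n):
            if is_genome[u]:
                kg[lab[u]] += k[u]
                for idx in range(indptr[u], indptr[u + 1]):
                    E[lab[u], lab[indices[idx]]] += 1.0
            else:
                kf[lab[u]] += k[u]
        cross = E + E.T
        dq = cross / L - (np.outer(kg, kf) + np.outer(kf, kg)) / (L * L)
        np.fill_diagonal(dq, -np.inf)
        best = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[best] <= 1e-12:
            return np.array([relab[m] for m in labels])
        a, b = int(best[0]), int(best[1])
        keep, drop = uniq[min(a, b)], uniq[max(a, b)]
        labels = labels.copy()
        labels[labels == drop] = keep


def _absorb_single_class_modules(labels, is_genome, indptr, indices, k, L):
    """Merge modules containing only one node class into their best
    neighbouring module whenever the merge is Q-neutral or better.

    Such modules (e.g. the lone genome of an isolated edge) can often be
    absorbed without changing Q; preferring the co-membered labelling makes
    the optimum unique on degenerate graphs."""
    n = labels.shape[0]
    while True:
        uniq, inv = np.unique(labels, return_inverse=True)
        nm = len(uniq)
        has_g = np.zeros(nm, dtype=bool)
        has_f = np.zeros(nm, dtype=bool)
        kg = np.zeros(nm)
        kf = np.zeros(nm)
        E = np.zeros((nm, nm))
        for u in range(n):
            m = inv[u]
            if is_genome[u]:
                has_g[m] = True
                kg[m] += k[u]
                for idx in range(indptr[u], indptr[u + 1]):
                    E[m, inv[indices[idx]]] += 1.0
            else:
                has_f[m] = True
                kf[m] += k[u]
        single = ~(has_g & has_f)
        if not single.any():
            return labels
        cross = E + E.T
        dq = cross / L - (np.outer(kg, kf) + np.outer(kf, kg)) / (L * L)
        np.fill_diagonal(dq, -np.inf)
        # only pairs involving a single-class module, sharing at least one edge
        allowed = (single[:, None] | single[None, :]) & (cross > 0)
        dq[~allowed] = -np.inf
        best = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[best] < -1e-12:
            return labels
        a, b = int(best[0]), int(best[1])
        keep, drop = uniq[min(a, b)], uniq[max(a, b)]
        labels = labels.copy()
        labels[labels == drop] = keep


def anneal_partition(
    network: BipartiteNetwork,
    seed: int,
    schedule: AnnealSchedule | None = None,
) -> Partition:
    """One simulated-annealing run; deterministic given ``seed``.

    The annealed labelling is polished by alternating deterministic greedy
    single-node sweeps and module-merge passes until neither improves Q, so
    the result is a local maximum under both move types.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    sched = schedule or AnnealSchedule()
    nodes, is_genome, indptr, indices, k = network.to_arrays()
    L = float(network.n_edges)
    seed32 = int(seed) % (2**31)
    t0 = sched.t0
    if t0 is None:
        t0 = float(
            _sa.calibrate_t0(indptr, indices, is_genome, k, L, seed32, 500)
        )
    labels, q = _sa.anneal(
        indptr,
        indices,
        is_genome,
        k,
        L,
        seed32,
        t0,
        sched.cooling,
        sched.moves_per_t_factor * len(nodes),
        sched.patience,
        sched.t_min_factor / L,
        sched.p_new_module,
        sched.max_blocks,
    )
    for _ in range(sched.merge_rounds):
        merged = _merge_pass(labels, is_genome, indptr, indices, k, L)
        kg = np.zeros(len(nodes))
        kf = np.zeros(len(nodes))
        size = np.zeros(len(nodes), dtype=np.int64)
        _sa._init_sums(merged, is_genome, k, kg, kf, size)
        gain = _sa.greedy_sweep(indptr, indices, merged, is_genome, k, kg, kf, size, L)
        labels = merged
        if gain <= 1e-12:
            break
    labels = _absorb_single_class_modules(labels, is_genome, indptr, indices, k, L)
    q = float(_sa.q_total(indptr, indices, labels, is_genome, k, L))
    # relabel modules consecutively in order of first appearance
    relab: dict[int, int] = {}
    final: dict[str, int] = {}
    for node, m in zip(nodes, labels.tolist()):
        final[node] = relab.setdefault(m, len(relab))
    return Partition(final, q)


@dataclass
class PartitionEnsemble:
    """Replicate partitions with the max-Q one flagged as best."""

    partitions: list[Partition]
    best_index: int
    genome_nodes: list[str]
    family_nodes: list[str]
    genome_coassignment: np.ndarray  # fraction of replicates co-assigning each pair
    family_coassignment: np.ndarray

    @property
    def best(self) -> Partition:
        return self.partitions[self.best_index]

    @property
    def n_replicates(self) -> int:
        return len(self.partitions)


def _coassignment(partitions: list[Partition], nodes: list[str]) -> np.ndarray:
    n = len(nodes)
    acc = np.zeros((n, n))
    for p in partitions:
        lab = np.array([p.labels[x] for x in nodes])
        acc += lab[:, None] == lab[None, :]
    return acc / len(partitions)


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def detect_modules(
    network: BipartiteNetwork,
    n_replicates: int = 100,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
) -> PartitionEnsemble:
    """Run ``n_replicates`` annealing replicates and keep the max-Q partition.

    Ties on Q are broken by the lowest replicate index, so the selection is
    deterministic given the master seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = replicate_seeds(seed, n_replicates)
    partitions = [anneal_partition(network, s, schedule) for s in seeds]
    best_index = 0
    for i, p in enumerate(partitions):
        if p.q > partitions[best_index].q + 1e-12:
            best_index = i
    return PartitionEnsemble(
        partitions,
        best_index,
        list(network.genomes),
        list(network.families),
        _coassignment(partitions, network.genomes),
        _coassignment(partitions, network.families),
    )


def degree_preserving_randomization(
    network: BipartiteNetwork, seed: int, n_swaps_factor: int = 10
) -> BipartiteNetwork:
    """Bipartite double-edge swap randomisation preserving every degree.

    Swaps (g1,f1),(g2,f2) → (g1,f2),(g2,f1), rejecting proposals that
    duplicate an existing edge.
    """
    edges = [
        (u, v) if u in set(network.genomes) else (v, u)
        for u, v in network.graph.edges()
    ]
    L = len(edges)
    if L < 2:
        raise ValueError("network too small to randomise by edge swaps")
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    target = n_swaps_factor * L
    done = 0
    attempts = 0
    max_attempts = 40 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, L, size=2)
        if i == j:
            continue
        g1, f1 = edges[i]
        g2, f2 = edges[j]
        if f1 == f2 or g1 == g2:
            continue
        if (g1, f2) in edge_set or (g2, f1) in edge_set:
            continue
        edge_set.discard((g1, f1))
        edge_set.discard((g2, f2))
        edge_set.add((g1, f2))
        edge_set.add((g2, f1))
        edges[i] = (g1, f2)
        edges[j] = (g2, f1)
        done += 1
    G = nx.Graph()
    G.add_nodes_from(network.genomes, bipartite=GENOME_CLASS)
    G.add_nodes_from(network.families, bipartite=FAMILY_CLASS)
    G.add_edges_from(edges)
    return BipartiteNetwork(G, list(network.genomes), list(network.families))


def partition_significance(
    network: BipartiteNetwork,
    observed_q: float,
    n_null: int = 100,
    seed: int = 0,
    n_replicates_per_null: int = 5,
    schedule: AnnealSchedule | None = None,
    n_swaps_factor: int = 10,
) -> float:
    """P value of ``observed_q`` against degree-preserving random networks.

    Each null network is optimised with ``n_replicates_per_null`` annealing
    replicates; the add-one estimator p = (1 + #{Q_null >= Q_obs}) /
    (1 + n_null) never reports zero.
    """
    if not math.isfinite(observed_q):
        raise ValueError("observed_q must be finite")
    seeds = replicate_seeds(seed ^ 0x5EED, n_null)
    exceed = 0
    for s in seeds:
        null_net = degree_preserving_randomization(network, s, n_swaps_factor)
        ens = detect_modules(null_net, n_replicates_per_null, seed=s, schedule=schedule)
        if ens.best.q >= observed_q:
            exceed += 1
    return (1 + exceed) / (1 + n_null)


def robustness_matrices(
    ensemble: PartitionEnsemble,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module robustness and module × module cross-similarity.

    Robustness of a module is the mean co-assignment fraction over its
    within-module pairs (genome pairs and family pairs separately; modules
    with no pair of a class default to 1).  Cross-similarity between two
    modules is the mean co-assignment fraction over genome pairs with one
    genome from each.
    """
    best = ensemble.best
    gidx = {g: i for i, g in enumerate(ensemble.genome_nodes)}
    fidx = {f: i for i, f in enumerate(ensemble.family_nodes)}
    modules = sorted(set(best.labels.values()))

    def _mean_within(members: list[int], co: np.ndarray) -> float:
        if len(members) < 2:
            return 1.0
        sub = co[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        return float(sub[iu].mean())

    rows = []
    gmembers: dict[int, list[int]] = {}
    for m in modules:
        gm = [gidx[n] for n in ensemble.genome_nodes if best.labels[n] == m]
        fm = [fidx[n] for n in ensemble.family_nodes if best.labels[n] == m]
        gmembers[m] = gm
        rg = _mean_within(gm, ensemble.genome_coassignment)
        rf = _mean_within(fm, ensemble.family_coassignment)
        rows.append((m, len(gm), len(fm), rg, rf))
    robustness = pd.DataFrame(
        rows,
        columns=[
            "module",
            "n_genomes",
            "n_families",
            "genome_robustness",
            "family_robustness",
        ],
    )
    cross = np.full((len(modules), len(modules)), np.nan)
    for a, ma in enumerate(modules):
        for b, mb in enumerate(modules):
            if a == b:
                cross[a, b] = 1.0
                continue
            if not gmembers[ma] or not gmembers[mb]:
                continue
            cross[a, b] = float(
                ensemble.genome_coassignment[np.ix_(gmembers[ma], gmembers[mb])].mean()
            )
    cross_df = pd.DataFrame(cross, index=modules, columns=modules)
    return robustness, cross_df


def reduced_schedule(schedule: AnnealSchedule | None = None) -> AnnealSchedule:
    """A cheaper schedule for per-null optimisation."""
    base = schedule or AnnealSchedule()
    return replace(base, cooling=0.98, patience=15, moves_per_t_factor=4)
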