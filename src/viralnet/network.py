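"""Bipartite genome–family network construction and degree statistics.

Genomes sharing more than 90% of their families (relative to the smaller
repertoire, ORFans included) are collapsed into pangenomes before the
network is built; the analysis universe is the giant component.  Degree
distributions of family nodes are summarised by a discrete maximum-
likelihood power-law exponent, and the bipartite clustering coefficient is
the Latapy pairwise neighbourhood-overlap (Jaccard) coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genomes import GenomeSet

GENOME_CLASS = 0
FAMILY_CLASS = 1


@dataclass
class BipartiteNetwork:
    """Undirected bipartite graph over genome and family nodes."""

    graph: nx.Graph
    genomes: list[str]
    families: list[str]
    dropped_nodes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self, node_class: int) -> dict[str, int]:
        nodes = self.genomes if node_class == GENOME_CLASS else self.families
        return {n: self.graph.degree(n) for n in nodes}

    def to_arrays(self):
        """CSR adjacency over a canonical node ordering (genomes first)."""
        nodes = list(self.genomes) + list(self.families)
        index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        is_genome = np.zeros(n, dtype=np.bool_)
        is_genome[: len(self.genomes)] = True
        neighbors: list[list[int]] = [[] for _ in range(n)]
        for u, v in self.graph.edges():
            iu, iv = index[u], index[v]
            neighbors[iu].append(iv)
            neighbors[iv].append(iu)
        indptr = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            neighbors[i].sort()
            indptr[i + 1] = indptr[i] + len(neighbors[i])
        indices = np.empty(indptr[-1], dtype=np.int64)
        for i in range(n):
            indices[indptr[i] : indptr[i + 1]] = neighbors[i]
        k = np.diff(indptr).astype(np.float64)
        return nodes, is_genome, indptr, indices, k


@dataclass
class DegreeProfile:
    """Degree (or clustering) summary for the two node classes."""

    genome_degrees: dict[str, int] = field(default_factory=dict)
    family_degrees: dict[str, int] = field(default_factory=dict)
    gamma: float | None = None  # family-degree power-law exponent
    k_min: int = 1
    n_tail: int = 0
    clustering: dict[str, float] = field(default_factory=dict)
    ck_curve: pd.DataFrame | None = None  # columns: k, mean_c, n
    alpha: float | None = None  # decay exponent of C(k)

    def histogram(self, node_class: int) -> dict[int, int]:
        degs = self.genome_degrees if node_class == GENOME_CLASS else self.family_degrees
        hist: dict[int, int] = {}
        for k in degs.values():
            hist[k] = hist.get(k, 0) + 1
        return hist


def shared_fraction(fi: frozenset, fj: frozenset) -> float:
    """Fraction of families shared, relative to the smaller repertoire."""
    if not fi or not fj:
        raise ValueError("genomes must be non-empty")
    return len(fi & fj) / min(len(fi), len(fj))


def merge_redundant_genomes(
    genomes: GenomeSet, share_threshold: float = 0.9
) -> GenomeSet:
    """Collapse genomes sharing more than ``share_threshold`` of their families.

    Sharing is |F_i ∩ F_j| / min(|F_i|, |F_j|), ORFans included; merging is
    transitive (single linkage).  A pangenome's family set is the union of
    its members, its id the lexicographically smallest member id, and the
    member ids are recorded in ``GenomeSet.members``.
    """
    if not 0.0 < share_threshold <= 1.0:
        raise ValueError("share_threshold must be in (0, 1]")
    gids = genomes.genome_ids
    fsets = genomes.family_sets()
    parent = {g: g for g in gids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, gi in enumerate(gids):
        for gj in gids[i + 1 :]:
            if find(gi) == find(gj):
                continue
            if shared_fraction(fsets[gi], fsets[gj]) > share_threshold:
                parent[find(gj)] = find(gi)

    clusters: dict[str, list[str]] = {}
    for g in gids:
        clusters.setdefault(find(g), []).append(g)

    memberships: dict[str, dict[str, int]] = {}
    members: dict[str, list[str]] = {}
    taxon: dict[str, str] = {}
    lifestyle: dict[str, str] = {}
    for group in clusters.values():
        group_members = sorted(
            m for g in group for m in genomes.members.get(g, [g])
        )
        pid = min(group)
        merged: dict[str, int] = {}
        for g in group:
            for fid, c in genomes.memberships[g].items():
                merged[fid] = max(merged.get(fid, 0), c)
        memberships[pid] = merged
        members[pid] = group_members
        if pid in genomes.taxon:
            taxon[pid] = genomes.taxon[pid]
        if pid in genomes.lifestyle:
            lifestyle[pid] = genomes.lifestyle[pid]
    return GenomeSet(memberships, taxon=taxon, lifestyle=lifestyle, members=members)


def build_bipartite_network(
    genomes: GenomeSet, giant_only: bool = True
) -> BipartiteNetwork:
    """Connect each genome to every family it contains (presence-based edges).

    With ``giant_only`` the largest connected component (by node count) is
    retained and the dropped nodes are recorded.
    """
    overlap = set(genomes.genome_ids) & set(genomes.family_ids)
    if overlap:
        raise ValueError(f"genome and family ids overlap: {sorted(overlap)[:5]}")
    G = nx.Graph()
    G.add_nodes_from(genomes.genome_ids, bipartite=GENOME_CLASS)
    G.add_nodes_from(genomes.family_ids, bipartite=FAMILY_CLASS)
    for g, fams in genomes.memberships.items():
        for f in fams:
            G.add_edge(g, f)
    dropped: list[str] = []
    if giant_only and G.number_of_nodes() > 0:
        components = sorted(
            nx.connected_components(G), key=lambda c: (-len(c), min(c))
        )
        giant = components[0]
        dropped = sorted(n for n in G.nodes if n not in giant)
        G = G.subgraph(giant).copy()
    genome_nodes = [g for g in genomes.genome_ids if g in G]
    family_nodes = [f for f in genomes.family_ids if f in G]
    return BipartiteNetwork(G, genome_nodes, family_nodes, dropped)


def restrict_to_core(
    network: BipartiteNetwork, core_families: set[str]
) -> BipartiteNetwork:
    """Keep only family nodes in ``core_families`` and genomes still connected."""
    if not core_families:
        raise ValueError("core_families must be non-empty")
    keep_fams = [f for f in network.families if f in core_families]
    if not keep_fams:
        raise ValueError("no core family present in the network")
    G = network.graph.subgraph(list(network.genomes) + keep_fams).copy()
    isolated = [g for g in network.genomes if G.degree(g) == 0]
    G.remove_nodes_from(isolated)
    genome_nodes = [g for g in network.genomes if g in G]
    dropped = sorted(
        set(network.genomes + network.families) - set(genome_nodes) - set(keep_fams)
    )
    return BipartiteNetwork(G, genome_nodes, keep_fams, dropped)


def fit_powerlaw_discrete_ml(degrees, k_min: int = 1) -> float | None:
    """Discrete maximum-likelihood power-law exponent for P(k) ~ k^-gamma.

    Maximises the zeta likelihood -gamma * Σ ln k_i - n * ln ζ(gamma, k_min)
    over degrees >= ``k_min``.  (The familiar closed form
    1 + n / Σ ln(k_i / (k_min - 1/2)) approximates this but is visibly
    biased at k_min = 1, so the exact likelihood is used.)  Returns None
    when the tail is degenerate (fewer than 2 values, or all equal).
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    ks = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    if ks.size < 2 or np.all(ks == ks[0]):
        return None
    mean_log = float(np.mean(np.log(ks)))

    def nll(gamma: float) -> float:
        return gamma * mean_log + math.log(zeta(gamma, k_min))

    res = minimize_scalar(nll, bounds=(1.0 + 1e-6, 20.0), method="bounded")
    return float(res.x)


def degree_statistics(network: BipartiteNetwork, k_min: int = 1) -> DegreeProfile:
    """Per-class degrees and the family-degree power-law exponent γ."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    gdeg = network.degrees(GENOME_CLASS)
    fdeg = network.degrees(FAMILY_CLASS)
    fam_ks = list(fdeg.values())
    gamma = fit_powerlaw_discrete_ml(fam_ks, k_min=k_min)
    return DegreeProfile(
        genome_degrees=gdeg,
        family_degrees=fdeg,
        gamma=gamma,
        k_min=k_min,
        n_tail=sum(1 for k in fam_ks if k >= k_min),
    )


def bipartite_clustering(network: BipartiteNetwork) -> dict[str, float]:
    """Pairwise neighbourhood-overlap clustering coefficient per node.

    c(u) is the mean Jaccard overlap |N(u) ∩ N(v)| / |N(u) ∪ N(v)| over all
    distance-2 neighbours v of u.  Nodes with no distance-2 neighbour have an
    undefined coefficient, reported as NaN.
    """
    G = network.graph
    coeffs: dict[str, float] = {}
    for u in G.nodes:
        nu = set(G[u])
        second = {w for v in nu for w in G[v]} - {u}
        if not second:
            coeffs[u] = float("nan")
            continue
        total = 0.0
        for v in second:
            nv = set(G[v])
            total += len(nu & nv) / len(nu | nv)
        coeffs[u] = total / len(second)
    return coeffs


def clustering_profile(network: BipartiteNetwork) -> DegreeProfile:
    """C(k) curve (mean clustering per degree) and its log–log decay exponent α."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    coeffs = bipartite_clustering(network)
    rows = []
    by_k: dict[int, list[float]] = {}
    for node, c in coeffs.items():
        if math.isnan(c):
            continue
        by_k.setdefault(network.graph.degree(node), []).append(c)
    for k in sorted(by_k):
        vals = by_k[k]
        rows.append((k, float(np.mean(vals)), len(vals)))
    curve = pd.DataFrame(rows, columns=["k", "mean_c", "n"])
    alpha = None
    fit = curve[(curve["k"] > 0) & (curve["mean_c"] > 0)]
    if len(fit) >= 2:
        slope = np.polyfit(np.log(fit["k"]), np.log(fit["mean_c"]), 1)[0]
        alpha = -float(slope)
    prof = degree_statistics(network)
    prof.clustering = coeffs
    prof.ck_curve = curve
    prof.alpha = alpha
    return prof


def write_network(network: BipartiteNetwork, edge_path, graphml_path=None) -> None:
    pd.DataFrame(
        sorted(network.graph.edges()), columns=["genome_or_module", "family"]
    ).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(network.graph, graphml_path)
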