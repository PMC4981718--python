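"""Connector genes, module-level networks, and the supermodule hierarchy.

A family is a *connector* when its weighted prevalence exceeds ``exp(-1)``
in at least two modules.  Qualifying families and the modules they qualify
in define a higher-order bipartite network (module nodes × family nodes);
re-running module detection on it groups primary modules into supermodules.
Iterating this — merging (super)modules whose module-network nodes are
co-assigned in at least half of the replicate partitions — yields a merge
tree over the primary modules, annotated with iteration depth and merge
robustness.  Iteration stops when no merger occurs or the module-network
modularity is no longer significant against the degree-preserving null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genomes import GenomeSet
from .modularity import (
    AnnealSchedule,
    Partition,
    PartitionEnsemble,
    detect_modules,
    partition_significance,
    reduced_schedule,
)
from .network import BipartiteNetwork, FAMILY_CLASS, GENOME_CLASS
from .weights import prevalence_table

CONNECTOR_THRESHOLD = math.exp(-1)


@dataclass
class ConnectorTable:
    """Per-family module prevalences and the connector classification."""

    prevalence: pd.DataFrame  # families × modules (weighted prevalence)
    threshold: float

    @property
    def qualifying(self) -> dict[str, list]:
        mask = self.prevalence > self.threshold
        return {
            f: list(self.prevalence.columns[mask.loc[f].to_numpy()])
            for f in self.prevalence.index
        }

    @property
    def connectors(self) -> set[str]:
        mask = self.prevalence > self.threshold
        return set(self.prevalence.index[(mask.sum(axis=1) >= 2).to_numpy()])

    @property
    def retained(self) -> set[str]:
        """Families qualifying in >= 1 module (kept in the module network)."""
        mask = self.prevalence > self.threshold
        return set(self.prevalence.index[(mask.sum(axis=1) >= 1).to_numpy()])


def identify_connectors(
    partition: Partition | dict,
    genomes: GenomeSet,
    weights: pd.Series,
    threshold: float = CONNECTOR_THRESHOLD,
    network: BipartiteNetwork | None = None,
) -> ConnectorTable:
    """Weighted per-module prevalence of every family; connectors qualify in >= 2.

    ``partition`` may be a :class:`Partition` (genome groups are its modules
    with at least one genome) or a ready module → genome-set mapping.
    """
    if isinstance(partition, Partition):
        if network is None:
            groups: dict = {}
            for node, m in partition.labels.items():
                if node in genomes.memberships:
                    groups.setdefault(m, set()).add(node)
        else:
            groups = partition.genome_modules(network)
    else:
        groups = dict(partition)
    groups = {m: g for m, g in groups.items() if g}
    prev = prevalence_table(genomes, {str(m): g for m, g in groups.items()}, weights)
    return ConnectorTable(prev, threshold)


def build_module_network(connectors: ConnectorTable) -> BipartiteNetwork:
    """Bipartite network of modules × families with prevalence > threshold.

    Families qualifying in a single module are kept (degree-1 nodes) even
    though they are not connectors.
    """
    mask = connectors.prevalence > connectors.threshold
    qualifying = mask.sum(axis=1) >= 1
    if not qualifying.any():
        raise ValueError("no family qualifies in any module")
    module_nodes = [f"module::{m}" for m in connectors.prevalence.columns]
    G = nx.Graph()
    G.add_nodes_from(module_nodes, bipartite=GENOME_CLASS)
    fams = list(connectors.prevalence.index[qualifying.to_numpy()])
    G.add_nodes_from(fams, bipartite=FAMILY_CLASS)
    for f in fams:
        for m in connectors.prevalence.columns[mask.loc[f].to_numpy()]:
            G.add_edge(f"module::{m}", f)
    used_modules = [m for m in module_nodes if G.degree(m) > 0]
    G.remove_nodes_from([m for m in module_nodes if G.degree(m) == 0])
    return BipartiteNetwork(G, used_modules, fams)


@dataclass
class HierarchyNode:
    """A node of the merge tree: a primary module (leaf) or a merger."""

    node_id: str
    children: list[str] = field(default_factory=list)
    depth: int = 0  # iteration at which the merge happened; 0 for leaves
    robustness: float | None = None  # mean co-assignment supporting the merge


@dataclass
class HierarchyTree:
    """Forest over primary modules built by iterated module detection."""

    nodes: dict[str, HierarchyNode]
    roots: list[str]
    group_genomes: dict[str, set[str]]  # node_id -> genomes under it
    near_merges: pd.DataFrame  # pairs co-assigned in [band) but below threshold
    stop_reason: str = ""
    iterations: int = 0
    significance: list[float | None] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        return [n for n, node in self.nodes.items() if not node.children]

    def supermodules(self) -> dict[str, set[str]]:
        """Top-level groups (roots) → genome sets."""
        return {r: self.group_genomes[r] for r in self.roots}

    def leaf_descendants(self, node_id: str) -> list[str]:
        node = self.nodes[node_id]
        if not node.children:
            return [node_id]
        out: list[str] = []
        for c in node.children:
            out.extend(self.leaf_descendants(c))
        return out

    def to_newick(self) -> str:
        def render(nid: str, parent_depth: int) -> str:
            node = self.nodes[nid]
            length = parent_depth - node.depth
            if not node.children:
                return f"{nid}:{length}"
            inner = ",".join(render(c, node.depth) for c in node.children)
            label = "" if node.robustness is None else f"{node.robustness:.2f}"
            return f"({inner}){label}:{length}"

        top_depth = self.iterations
        parts = [render(r, top_depth) for r in self.roots]
        if len(parts) == 1:
            return parts[0] + ";"
        return "(" + ",".join(parts) + ");"


def detect_supermodules(
    primary_partition: Partition,
    genomes: GenomeSet,
    weights: pd.Series,
    *,
    network: BipartiteNetwork | None = None,
    seed: int = 0,
    n_replicates: int = 100,
    n_null: int = 100,
    n_replicates_per_null: int = 5,
    merge_threshold: float = 0.5,
    near_merge_band: tuple[float, float] = (0.25, 0.5),
    connector_threshold: float = CONNECTOR_THRESHOLD,
    significance_alpha: float = 0.01,
    max_iterations: int = 10,
    schedule: AnnealSchedule | None = None,
) -> HierarchyTree:
    """Iterate module-network detection into a hierarchy of supermodules.

    At each iteration the current groups' prevalence network is built and
    partitioned (``n_replicates`` replicates); groups whose nodes co-occur
    in at least ``merge_threshold`` of the replicates are merged (single
    linkage over qualifying pairs), with the merge's robustness recorded as
    the mean pairwise co-assignment.  Pairs inside ``near_merge_band`` are
    reported but not merged.
    """
    if isinstance(primary_partition, Partition):
        if network is not None:
            base_groups = primary_partition.genome_modules(network)
        else:
            base_groups = {}
            for node, m in primary_partition.labels.items():
                if node in genomes.memberships:
                    base_groups.setdefault(m, set()).add(node)
    else:
        base_groups = dict(primary_partition)

    nodes: dict[str, HierarchyNode] = {}
    group_genomes: dict[str, set[str]] = {}
    current: dict[str, set[str]] = {}
    for m, gset in sorted(base_groups.items(), key=lambda kv: str(kv[0])):
        nid = f"M{m}"
        nodes[nid] = HierarchyNode(nid)
        group_genomes[nid] = set(gset)
        current[nid] = set(gset)

    near_rows: list[tuple] = []
    significance: list[float | None] = []
    stop_reason = ""
    iteration = 0
    rng_seeds = np.random.SeedSequence(seed).generate_state(
        2 * max_iterations, dtype=np.uint32
    )

    while iteration < max_iterations:
        if len(current) < 2:
            stop_reason = "single group remains"
            break
        conn = identify_connectors(current, genomes, weights, connector_threshold)
        try:
            mod_net = build_module_network(conn)
        except ValueError:
            stop_reason = "no connector genes"
            break
        present = set(mod_net.genomes)
        if len(present) < 2 or mod_net.n_edges == 0:
            stop_reason = "no connector genes"
            break
        it_seed = int(rng_seeds[2 * iteration]) % (2**31)
        ens = detect_modules(mod_net, n_replicates, seed=it_seed, schedule=schedule)
        p_value: float | None = None
        if n_null > 0:
            try:
                p_value = partition_significance(
                    mod_net,
                    ens.best.q,
                    n_null=n_null,
                    seed=int(rng_seeds[2 * iteration + 1]) % (2**31),
                    n_replicates_per_null=n_replicates_per_null,
                    schedule=reduced_schedule(schedule),
                )
            except ValueError:
                p_value = None  # module network too small to randomise
        significance.append(p_value)
        if p_value is not None and p_value >= significance_alpha:
            stop_reason = "nonsignificant modularity"
            break

        # co-assignment fractions among module-class nodes
        mod_ids = [n.removeprefix("module::") for n in ens.genome_nodes]
        co = ens.genome_coassignment
        parent_of = {m: m for m in current}

        def find(x):
            while parent_of[x] != x:
                parent_of[x] = parent_of[parent_of[x]]
                x = parent_of[x]
            return x

        merged_any = False
        for i in range(len(mod_ids)):
            for j in range(i + 1, len(mod_ids)):
                a, b = mod_ids[i], mod_ids[j]
                if co[i, j] >= merge_threshold:
                    if find(a) != find(b):
                        parent_of[find(b)] = find(a)
                        merged_any = True
                elif near_merge_band[0] <= co[i, j] < near_merge_band[1]:
                    near_rows.append((iteration + 1, a, b, float(co[i, j])))
        if not merged_any:
            stop_reason = "no merger"
            break

        iteration += 1
        clusters: dict[str, list[str]] = {}
        for m in current:
            clusters.setdefault(find(m), []).append(m)
        idx_of = {m: i for i, m in enumerate(mod_ids)}
        new_current: dict[str, set[str]] = {}
        for root, members in sorted(clusters.items()):
            if len(members) == 1:
                new_current[members[0]] = current[members[0]]
                continue
            nid = f"H{iteration}.{len(new_current)}"
            pairs = [
                co[idx_of[a], idx_of[b]]
                for x, a in enumerate(members)
                for b in members[x + 1 :]
                if a in idx_of and b in idx_of
            ]
            rob = float(np.mean(pairs)) if pairs else 1.0
            union = set().union(*(current[m] for m in members))
            nodes[nid] = HierarchyNode(
                nid, children=sorted(members), depth=iteration, robustness=rob
            )
            group_genomes[nid] = union
            new_current[nid] = union
        current = new_current
    else:
        stop_reason = "max iterations reached"

    near = pd.DataFrame(
        near_rows, columns=["iteration", "group_a", "group_b", "co_assignment"]
    )
    return HierarchyTree(
        nodes=nodes,
        roots=sorted(current),
        group_genomes=group_genomes,
        near_merges=near,
        stop_reason=stop_reason,
        iterations=iteration,
        significance=significance,
    )


def dissect_subnetwork(
    network: BipartiteNetwork,
    module_ids: set,
    partition: Partition,
    n_replicates: int = 100,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
) -> tuple[BipartiteNetwork, PartitionEnsemble]:
    """Re-analyse the subnetwork of chosen modules at higher resolution.

    The subnetwork contains the genomes assigned to ``module_ids`` plus all
    families connected (not necessarily assigned) to them.
    """
    assigned = set(partition.labels.values())
    missing = set(module_ids) - assigned
    if missing:
        raise ValueError(f"module id(s) not in partition: {sorted(missing)}")
    sub_genomes = [
        g for g in network.genomes if partition.labels[g] in set(module_ids)
    ]
    if not sub_genomes:
        raise ValueError("no genomes in the requested modules")
    fams = sorted({f for g in sub_genomes for f in network.graph[g]})
    G = network.graph.subgraph(sub_genomes + fams).copy()
    sub = BipartiteNetwork(G, sub_genomes, fams)
    return sub, detect_modules(sub, n_replicates, seed=seed, schedule=schedule)
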