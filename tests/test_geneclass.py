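"""Gene classification (hallmark/connector/signature) and betweenness shares."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from viralnet.geneclass import (
    betweenness_accounting,
    classify_hallmark,
    classify_signature,
    mi_table,
    mutual_information_cells,
    normalized_mutual_information,
)
from viralnet.genomes import GenomeSet
from viralnet.hierarchy import ConnectorTable
from .conftest import make_network


def _uniform(gs):
    return pd.Series(1.0 / gs.n_genomes, index=gs.genome_ids)


class TestMutualInformation:
    def test_perfect_match_is_one(self):
        # gene coextensive with a module of weight 0.25
        assert abs(mutual_information_cells(0.25, 0.0, 0.0, 0.75) - 1.0) < 1e-12

    def test_independence_is_zero(self):
        assert abs(mutual_information_cells(0.125, 0.375, 0.125, 0.375)) < 1e-12

    def test_half_module_case_matches_direct_formula(self):
        a, b, c, d = 0.25, 0.0, 0.25, 0.5
        mi = a * math.log2(a / ((a + b) * (a + c))) + d * math.log2(
            d / ((c + d) * (b + d))
        )
        h = -sum(x * math.log2(x) for x in (a, c, d))
        assert abs(mutual_information_cells(a, b, c, d) - mi / h) < 1e-12

    def test_degenerate_single_cell_mass_is_zero(self):
        assert mutual_information_cells(1.0, 0.0, 0.0, 0.0) == 0.0

    def test_cells_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mutual_information_cells(0.5, 0.5, 0.5, 0.5)

    def test_pattern_api_agrees_with_cells(self):
        gs = GenomeSet(
            {
                "a": {"f": 1, "x": 1},
                "b": {"f": 1},
                "c": {"y": 1},
                "d": {"z": 1},
            }
        )
        w = _uniform(gs)
        got = normalized_mutual_information("f", {"a", "b"}, gs, w)
        assert abs(got - 1.0) < 1e-12  # coextensive with the module
        table = mi_table(gs, {"m": {"a", "b"}}, w)
        assert abs(table.loc["f", "m"] - 1.0) < 1e-12


class TestHallmark:
    def _connectors(self, prevalences):
        prev = pd.DataFrame(prevalences)
        return ConnectorTable(prev, math.exp(-1))

    def _genomes(self):
        gs = GenomeSet(
            {
                "a": {"hall": 1, "x1": 1},
                "b": {"hall": 1, "x2": 1},
                "c": {"x3": 1},
                "d": {"hall": 1, "y1": 1},
                "e": {"y2": 1},
                "f": {"y3": 1},
            }
        )
        return gs, _uniform(gs)

    def test_prevalent_connector_is_hallmark(self):
        gs, w = self._genomes()
        conn = self._connectors(
            {"m1": {"hall": 0.6, "solo": 0.9}, "m2": {"hall": 0.5, "solo": 0.0}}
        )
        supermods = {"S1": {"a", "b", "c"}, "S2": {"d", "e", "f"}}
        out = classify_hallmark(conn, supermods, gs, w).set_index("family_id")
        assert out.loc["hall", "hallmark"]
        # "solo" is prevalent but qualifies in one module only -> not hallmark
        assert not out.loc["solo", "hallmark"]

    def test_low_supermodule_prevalence_blocks_hallmark(self):
        gs = GenomeSet(
            {
                "a": {"c1": 1, "p1": 1},
                "b": {"p2": 1},
                "c": {"p3": 1},
                "d": {"p4": 1},
                "e": {"c1": 1, "p5": 1},
                "f": {"p6": 1},
                "g": {"p7": 1},
                "h": {"p8": 1},
            }
        )
        w = _uniform(gs)
        conn = self._connectors({"m1": {"c1": 0.9}, "m2": {"c1": 0.9}})
        # one carrier per supermodule of 4: prevalence 0.25 < 0.35 in both
        supermods = {"S1": {"a", "b", "c", "d"}, "S2": {"e", "f", "g", "h"}}
        out = classify_hallmark(conn, supermods, gs, w).set_index("family_id")
        assert out.loc["c1", "connector"]
        assert not out.loc["c1", "hallmark"]

    def test_fewer_than_two_supermodules_empty_hallmark_set(self):
        gs, w = self._genomes()
        conn = self._connectors({"m1": {"hall": 0.9}, "m2": {"hall": 0.9}})
        out = classify_hallmark(conn, {"S1": set(gs.genome_ids)}, gs, w)
        assert not out["hallmark"].any()

    def test_major_supermodules_are_two_largest(self):
        gs = GenomeSet(
            {g: {"hall": 1, f"p{g}": 1} if g in "ab" else {f"p{g}": 1}
             for g in "abcdefgh"}
        )
        w = _uniform(gs)
        conn = self._connectors({"m1": {"hall": 0.9}, "m2": {"hall": 0.9}})
        # hall prevalent only in the smallest supermodule S3 -> not hallmark
        supermods = {"S1": {"c", "d", "e"}, "S2": {"f", "g", "h"}, "S3": {"a", "b"}}
        out = classify_hallmark(conn, supermods, gs, w).set_index("family_id")
        assert not out.loc["hall", "hallmark"]


class TestSignature:
    def test_threshold_logic(self):
        mi = pd.DataFrame(
            {
                "m1": [0.7, 1.0, 0.5, 0.65],
                "m2": [0.01, 0.0, 0.0, 0.05],
            },
            index=["sig", "perfect", "low_best", "high_second"],
        )
        out = classify_signature(mi)
        assert out.loc["sig", "signature"]
        assert out.loc["perfect", "signature"]
        assert not out.loc["low_best", "signature"]
        assert not out.loc["high_second", "signature"]
        assert out.loc["sig", "best_module"] == "m1"

    def test_single_module_second_mi_defaults_to_zero(self):
        mi = pd.DataFrame({"m1": [0.8]}, index=["f"])
        out = classify_signature(mi)
        assert out.loc["f", "mi_second"] == 0.0
        assert out.loc["f", "signature"]

    def test_exclusive_planted_family_is_signature(self):
        gs = GenomeSet(
            {
                "a": {"sig": 1, "n1": 1},
                "b": {"sig": 1, "n2": 1},
                "c": {"n3": 1},
                "d": {"n4": 1},
            }
        )
        w = _uniform(gs)
        mi = mi_table(gs, {"m1": {"a", "b"}, "m2": {"c", "d"}}, w)
        out = classify_signature(mi)
        assert out.loc["sig", "mi_best"] == pytest.approx(1.0)
        assert out.loc["sig", "signature"]


def brute_force_betweenness(G):
    """Exact betweenness by explicit shortest-path enumeration (small graphs)."""
    nodes = list(G.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


class TestBetweenness:
    def test_double_star_matches_path_enumeration(self):
        # hub family f0 linked to g1..g4; each genome has one private family
        net = make_network({f"g{i}": ["f0", f"p{i}"] for i in range(1, 5)})
        oracle = brute_force_betweenness(net.graph)
        classes = pd.DataFrame({"family_id": net.families, "gene_class": "other"})
        out = betweenness_accounting(net, classes)
        n = net.graph.number_of_nodes()
        norm = 2.0 / ((n - 1) * (n - 2))
        for node, val in oracle.items():
            assert out["node_betweenness"][node] == pytest.approx(val * norm)

    def test_complete_bipartite_gene_nodes_equal(self):
        net = make_network({f"g{i}": ["f1", "f2", "f3"] for i in range(3)})
        classes = pd.DataFrame({"family_id": net.families, "gene_class": "other"})
        out = betweenness_accounting(net, classes)
        vals = [out["node_betweenness"][f] for f in net.families]
        assert max(vals) - min(vals) < 1e-12

    def test_bridge_class_dominates_shares(self):
        # two blocks joined only through family "bridge" (class hallmark)
        memberships = {f"a{i}": {"fa": 1, "bridge": 1} for i in range(3)}
        memberships |= {f"b{i}": {"fb": 1, "bridge": 1} for i in range(3)}
        net = make_network({g: list(f) for g, f in memberships.items()})
        classes = pd.DataFrame(
            {
                "family_id": net.families,
                "gene_class": ["hallmark" if f == "bridge" else "other" for f in net.families],
            }
        )
        out = betweenness_accounting(net, classes)
        assert out["class_shares"]["hallmark"] > out["class_shares"].get("other", 0.0)

    def test_random_graphs_match_enumeration(self):
        rng = np.random.default_rng(4)
        from .conftest import random_bipartite

        for _ in range(10):
            net = random_bipartite(rng, max_side=5)
            oracle = brute_force_betweenness(net.graph)
            classes = pd.DataFrame({"family_id": net.families, "gene_class": "other"})
            out = betweenness_accounting(net, classes)
            n = net.graph.number_of_nodes()
            if n < 3:
                continue
            norm = 2.0 / ((n - 1) * (n - 2))
            for node, val in oracle.items():
                assert out["node_betweenness"][node] == pytest.approx(val * norm)
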