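"""Connector genes, module networks, and the supermodule hierarchy."""

import math

import numpy as np
import pandas as pd
import pytest

import viralnet as vn
from viralnet.genomes import GenomeSet
from viralnet.hierarchy import (
    ConnectorTable,
    build_module_network,
    detect_supermodules,
    dissect_subnetwork,
    identify_connectors,
)


def _uniform_weights(gs):
    return pd.Series(1.0 / gs.n_genomes, index=gs.genome_ids)


class TestConnectors:
    def _toy(self):
        # modules m1 = {a,b}, m2 = {c,d}; families with known prevalences
        gs = GenomeSet(
            {
                "a": {"both": 1, "half": 1, "solo": 1},
                "b": {"both": 1, "weak": 1},
                "c": {"both": 1, "half": 1, "weak": 1},
                "d": {"both": 1, "solo2": 1},
            }
        )
        groups = {"m1": {"a", "b"}, "m2": {"c", "d"}}
        return gs, groups, _uniform_weights(gs)

    def test_full_prevalence_in_two_modules_is_connector(self):
        gs, groups, w = self._toy()
        table = identify_connectors(groups, gs, w)
        assert "both" in table.connectors

    def test_prevalence_below_threshold_not_connector(self):
        gs, groups, w = self._toy()
        table = identify_connectors(groups, gs, w)
        # "weak": prevalence 0.5 in each module -> above exp(-1), connector;
        # "solo": 0.5 in m1 only -> retained, not a connector
        assert "weak" in table.connectors
        assert "solo" not in table.connectors
        assert "solo" in table.retained

    def test_threshold_comparison_is_strict(self):
        gs = GenomeSet(
            {
                "a": {"f": 1, "p1": 1},
                "b": {"p2": 1},
                "c": {"p3": 1},
                "d": {"f": 1, "p4": 1},
            }
        )
        groups = {"m1": {"a", "b", "c"}, "m2": {"d"}}
        w = _uniform_weights(gs)
        table = identify_connectors(groups, gs, w)
        # prevalence of f in m1 = 1/3 < exp(-1) -> qualifies only in m2
        assert "f" not in table.connectors
        assert table.qualifying["f"] == ["m2"]

    def test_both_above_threshold_is_connector(self):
        gs = GenomeSet(
            {
                "a": {"f": 1, "x1": 1},
                "b": {"f": 1, "x2": 1},
                "c": {"x3": 1},
                "d": {"x4": 1},
                "e": {"f": 1, "y1": 1},
                "g": {"f": 1, "y2": 1},
                "h": {"y3": 1},
                "i": {"y4": 1},
                "j": {"y5": 1},
            }
        )
        groups = {"m1": {"a", "b", "c", "d"}, "m2": {"e", "g", "h", "i", "j"}}
        table = identify_connectors(groups, gs, _uniform_weights(gs))
        # prevalences 0.5 and 0.4, both > exp(-1) ~ 0.368
        assert abs(table.prevalence.loc["f", "m1"] - 0.5) < 1e-12
        assert abs(table.prevalence.loc["f", "m2"] - 0.4) < 1e-12
        assert "f" in table.connectors


class TestModuleNetwork:
    def test_k23_from_three_shared_connectors(self):
        prev = pd.DataFrame(
            {"m1": [1.0, 1.0, 1.0], "m2": [1.0, 1.0, 1.0]},
            index=["c1", "c2", "c3"],
        )
        net = build_module_network(ConnectorTable(prev, math.exp(-1)))
        assert len(net.genomes) == 2 and len(net.families) == 3
        assert net.n_edges == 6

    def test_single_module_family_kept_as_degree_one(self):
        prev = pd.DataFrame({"m1": [1.0, 1.0], "m2": [1.0, 0.0]}, index=["c", "s"])
        net = build_module_network(ConnectorTable(prev, math.exp(-1)))
        assert net.graph.degree("s") == 1

    def test_empty_table_rejected(self):
        prev = pd.DataFrame({"m1": [0.1], "m2": [0.2]}, index=["f"])
        with pytest.raises(ValueError):
            build_module_network(ConnectorTable(prev, math.exp(-1)))


class TestSupermodules:
    def _planted(self, **kw):
        defaults = dict(
            n_supermodules=2,
            modules_per_supermodule=3,
            genomes_per_module=10,
            n_signature_per_module=5,
            p_signature=1.0,
            n_connector_per_module_pair=3,
            p_connector=1.0,
            n_hallmark_per_supermodule=8,
            p_hallmark=1.0,
            n_orfans_per_genome=2,
            n_noise_families=0,
            seed=17,
        )
        defaults.update(kw)
        cfg = vn.PlantedConfig(**defaults)
        gs, truth = vn.generate_planted_network(cfg)
        modules = {}
        for g, m in truth.genome_module.items():
            modules.setdefault(m, set()).add(g)
        return gs, truth, modules

    def test_two_planted_supermodules_merge_at_depth_one(self):
        gs, truth, modules = self._planted()
        w = _uniform_weights(gs)
        tree = detect_supermodules(
            modules, gs, w, seed=3, n_replicates=100, n_null=100
        )
        merges = [n for n in tree.nodes.values() if n.children]
        assert len(merges) == 2
        assert all(n.depth == 1 and n.robustness == 1.0 for n in merges)
        for r in tree.roots:
            covered = {truth.genome_supermodule[g] for g in tree.group_genomes[r]}
            assert len(covered) == 1

    def test_no_connectors_yields_flat_tree(self):
        gs, truth, modules = self._planted(
            n_connector_per_module_pair=0, n_hallmark_per_supermodule=0
        )
        w = _uniform_weights(gs)
        tree = detect_supermodules(modules, gs, w, seed=3, n_replicates=20, n_null=20)
        assert sorted(tree.roots) == sorted(f"M{m}" for m in modules)
        assert tree.iterations == 0

    def test_leaves_cover_all_primary_modules_once(self):
        gs, truth, modules = self._planted()
        w = _uniform_weights(gs)
        tree = detect_supermodules(modules, gs, w, seed=5, n_replicates=50, n_null=0)
        leaf_sets = [leaf for r in tree.roots for leaf in tree.leaf_descendants(r)]
        assert sorted(leaf_sets) == sorted(f"M{m}" for m in modules)

    def test_newick_roundtrips_through_skbio(self):
        gs, truth, modules = self._planted()
        w = _uniform_weights(gs)
        tree = detect_supermodules(modules, gs, w, seed=5, n_replicates=50, n_null=0)
        import io
        from skbio import TreeNode

        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == set(tree.leaves)

    def test_raising_merge_threshold_never_adds_merges(self):
        gs, truth, modules = self._planted(p_connector=0.9, p_hallmark=0.9)
        w = _uniform_weights(gs)
        lo = detect_supermodules(
            modules, gs, w, seed=7, n_replicates=30, n_null=0, merge_threshold=0.5
        )
        hi = detect_supermodules(
            modules, gs, w, seed=7, n_replicates=30, n_null=0, merge_threshold=0.9
        )
        n_merges_lo = sum(1 for n in lo.nodes.values() if n.children)
        n_merges_hi = sum(1 for n in hi.nodes.values() if n.children)
        assert n_merges_hi <= n_merges_lo


class TestDissection:
    def test_whole_network_dissection_is_identity(self, two_k22_blocks):
        ens = vn.detect_modules(two_k22_blocks, 10, seed=1)
        best = ens.best
        sub, sub_ens = dissect_subnetwork(
            two_k22_blocks, set(best.labels.values()), best, n_replicates=10, seed=1
        )
        assert sub.n_edges == two_k22_blocks.n_edges
        assert abs(sub_ens.best.q - ens.best.q) < 1e-12

    def test_unknown_module_rejected(self, two_k22_blocks):
        ens = vn.detect_modules(two_k22_blocks, 5, seed=1)
        with pytest.raises(ValueError):
            dissect_subnetwork(two_k22_blocks, {999}, ens.best, 5, seed=0)

    def test_nested_submodules_revealed_at_higher_resolution(self):
        # two sub-blocks weakly tied into one apparent module plus a large
        # backdrop; dissection of the merged module splits it in two
        memberships = {}
        for i in range(6):
            memberships[f"x{i}"] = {f"fx{j}": 1 for j in range(8)} | {"tie": 1}
        for i in range(6):
            memberships[f"y{i}"] = {f"fy{j}": 1 for j in range(8)} | {"tie": 1}
        gs = GenomeSet(memberships)
        net = vn.build_bipartite_network(gs)
        ens = vn.detect_modules(net, 20, seed=2)
        labels = {ens.best.labels[g] for g in net.genomes}
        sub, sub_ens = dissect_subnetwork(net, labels, ens.best, 20, seed=3)
        x_labels = {sub_ens.best.labels[f"x{i}"] for i in range(6)}
        y_labels = {sub_ens.best.labels[f"y{i}"] for i in range(6)}
        assert len(x_labels) == 1 and len(y_labels) == 1
        assert x_labels != y_labels
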