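"""Barber modularity, annealing, ensembles, null model and robustness."""

import numpy as np
import pytest

from viralnet.modularity import (
    AnnealSchedule,
    Partition,
    PartitionEnsemble,
    _coassignment,
    anneal_partition,
    barber_modularity,
    degree_preserving_randomization,
    detect_modules,
    partition_significance,
    reduced_schedule,
    robustness_matrices,
)
from .conftest import brute_force_best_q, make_network, random_bipartite


class TestBarberModularity:
    def test_trivial_partitions_have_zero_q(self, two_k22_blocks):
        net = two_k22_blocks
        one = {n: 0 for n in net.graph.nodes}
        singletons = {n: i for i, n in enumerate(net.graph.nodes)}
        assert abs(barber_modularity(net, one)) < 1e-12
        assert abs(barber_modularity(net, singletons)) < 1e-12

    def test_two_blocks_hand_value(self, two_k22_blocks):
        labels = {"g1": 0, "g2": 0, "f1": 0, "f2": 0, "g3": 1, "g4": 1, "f3": 1, "f4": 1}
        assert abs(barber_modularity(two_k22_blocks, labels) - 0.5) < 1e-12

    def test_missing_label_rejected(self, two_k22_blocks):
        with pytest.raises(ValueError):
            barber_modularity(two_k22_blocks, {"g1": 0})

    def test_q_within_bounds_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = random_bipartite(rng)
            labels = {n: int(rng.integers(0, 3)) for n in net.graph.nodes}
            q = barber_modularity(net, labels)
            assert -1.0 <= q <= 1.0


class TestAnnealing:
    def test_two_blocks_recovered_across_seeds(self, two_k22_blocks):
        hits = sum(
            abs(anneal_partition(two_k22_blocks, seed=s).q - 0.5) < 1e-12
            for s in range(100)
        )
        assert hits >= 95

    def test_single_edge_network_trivial(self):
        net = make_network({"g": ["f"]})
        p = anneal_partition(net, seed=0)
        assert p.labels["g"] == p.labels["f"]
        assert abs(p.q) < 1e-12

    def test_deterministic_given_seed(self, two_k22_blocks):
        a = anneal_partition(two_k22_blocks, seed=42)
        b = anneal_partition(two_k22_blocks, seed=42)
        assert a.labels == b.labels and a.q == b.q

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(cooling=1.5)
        with pytest.raises(ValueError):
            AnnealSchedule(t0=-1.0)

    def test_best_q_never_below_trivial(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_bipartite(rng)
            p = anneal_partition(net, seed=int(rng.integers(2**31)))
            assert p.q >= -1e-12

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            net = random_bipartite(rng, max_side=4)
            ens = detect_modules(net, 10, seed=int(rng.integers(2**31)))
            assert abs(ens.best.q - brute_force_best_q(net)) < 1e-9


class TestEnsembles:
    def test_deterministic_ensemble_and_tie_rule(self, two_k22_blocks):
        a = detect_modules(two_k22_blocks, 10, seed=1)
        b = detect_modules(two_k22_blocks, 10, seed=1)
        assert a.best_index == b.best_index
        assert [p.q for p in a.partitions] == [p.q for p in b.partitions]
        # all replicates find the optimum; tie broken by lowest index
        assert a.best_index == 0

    def test_single_replicate_robustness_one(self, two_k22_blocks):
        ens = detect_modules(two_k22_blocks, 1, seed=3)
        rob, cross = robustness_matrices(ens)
        assert (rob["genome_robustness"] == 1.0).all()
        assert (rob["family_robustness"] == 1.0).all()

    def test_coassignment_symmetric_unit_diagonal(self, two_k22_blocks):
        ens = detect_modules(two_k22_blocks, 5, seed=9)
        co = ens.genome_coassignment
        assert np.allclose(co, co.T)
        assert np.allclose(np.diag(co), 1.0)


class TestRobustnessCounting:
    def _manual_ensemble(self, labelings, nodes_g, nodes_f):
        partitions = [Partition(dict(lab), 0.0) for lab in labelings]
        # designate the first labeling as best (its Q does not matter here)
        return PartitionEnsemble(
            partitions,
            0,
            nodes_g,
            nodes_f,
            _coassignment(partitions, nodes_g),
            _coassignment(partitions, nodes_f),
        )

    def test_cross_similarity_half_when_merged_half_the_time(self):
        nodes_g, nodes_f = ["a", "b"], ["f"]
        together = {"a": 0, "b": 0, "f": 0}
        apart = {"a": 0, "b": 1, "f": 0}
        ens = self._manual_ensemble([apart] * 50 + [together] * 50, nodes_g, nodes_f)
        rob, cross = robustness_matrices(ens)
        assert abs(cross.loc[0, 1] - 0.5) < 1e-12

    def test_defecting_members_lower_robustness(self):
        # module {a,b,c,d}: c,d defect in every replicate after the first
        nodes_g = ["a", "b", "c", "d"]
        best = {"a": 0, "b": 0, "c": 0, "d": 0}
        defect = {"a": 0, "b": 0, "c": 1, "d": 1}
        ens = self._manual_ensemble([best] + [defect] * 9, nodes_g, [])
        rob, _ = robustness_matrices(ens)
        # pairs: ab=1.0, cd=1.0, ac=ad=bc=bd=0.1 -> mean = (2 + 4*0.1)/6
        expected = (2 * 1.0 + 4 * 0.1) / 6
        assert abs(rob.loc[rob["module"] == 0, "genome_robustness"].iloc[0] - expected) < 1e-12


class TestNullModel:
    def test_degrees_preserved_exactly(self, two_k22_blocks):
        import viralnet as vn

        gs, _ = vn.generate_planted_network(vn.PlantedConfig(seed=2))
        net = vn.build_bipartite_network(gs)
        null = degree_preserving_randomization(net, seed=11)
        for n in net.graph.nodes:
            assert net.graph.degree(n) == null.graph.degree(n)

    def test_too_small_to_swap_rejected(self):
        net = make_network({"g": ["f"]})
        with pytest.raises(ValueError):
            degree_preserving_randomization(net, seed=0)

    def test_infinite_observed_q_rejected(self, two_k22_blocks):
        with pytest.raises(ValueError):
            partition_significance(two_k22_blocks, float("inf"), n_null=5, seed=0)

    def test_modular_network_significant(self):
        import viralnet as vn

        cfg = vn.PlantedConfig(
            n_supermodules=4,
            modules_per_supermodule=1,
            genomes_per_module=8,
            n_signature_per_module=10,
            p_signature=0.95,
            n_connector_per_module_pair=0,
            n_hallmark_per_supermodule=0,
            n_orfans_per_genome=0,
            n_noise_families=8,
            p_noise=0.3,
            seed=21,
        )
        gs, _ = vn.generate_planted_network(cfg)
        net = vn.build_bipartite_network(gs)
        ens = detect_modules(net, 10, seed=1)
        p = partition_significance(
            net, ens.best.q, n_null=99, seed=2, n_replicates_per_null=3,
            schedule=reduced_schedule(),
        )
        assert p <= 0.01

    def test_null_self_consistency_at_matched_effort(self):
        # a degree-matched random network, optimised with the same effort as
        # its nulls, should not look significant
        import viralnet as vn

        gs, _ = vn.generate_planted_network(vn.PlantedConfig(seed=31))
        net = vn.build_bipartite_network(gs)
        random_net = degree_preserving_randomization(net, seed=5)
        ens = detect_modules(random_net, 3, seed=7, schedule=reduced_schedule())
        p = partition_significance(
            random_net, ens.best.q, n_null=19, seed=8, n_replicates_per_null=3,
            schedule=reduced_schedule(),
        )
        assert p >= 0.1
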