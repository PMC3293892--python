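"""Hub selection, knock-out/knock-down semantics and ground-truth derivation."""

import numpy as np
import pytest

from grnbench.disease_model import (
    KD,
    KO,
    assign_perturbations,
    build_cohorts,
    derive_truth,
    hub_reachable_genes,
    knock_down,
    knock_out,
    select_hubs,
)
from grnbench.grn_core import steady_state
from conftest import make_network


@pytest.fixture
def star_network():
    """Hub gene 0 activates genes 1..5 with varying strength; gene 6 isolated."""
    W = np.zeros((7, 7))
    W[1, 0] = 5.0
    W[2, 0] = 3.0
    W[3, 0] = 1.0
    W[4, 0] = 0.2
    W[5, 0] = 0.05
    # keep the hub itself highly expressed
    return make_network(W, bias=[4.0, -2.0, -1.5, -0.5, 0.0, 0.0, 1.0])


class TestHubSelection:
    def test_highest_out_degree_among_expressed(self):
        W = np.zeros((4, 4))
        W[1, 0] = W[2, 0] = W[3, 0] = 1.0  # gene 0: out-degree 3
        W[2, 1] = 1.0  # gene 1: out-degree 1
        net = make_network(W, bias=[5.0, 5.0, 5.0, 5.0])
        x = steady_state(net).x
        hubs = select_hubs(net, x, k=2, expr_min=0.88)
        assert hubs.gene_ids == (0, 1)
        assert hubs.out_degrees == (3, 1)

    def test_expression_filter_excludes_low_genes(self):
        W = np.zeros((3, 3))
        W[1, 0] = 1.0
        W[2, 1] = 1.0
        net = make_network(W, bias=[5.0, -5.0, 5.0])  # gene 1 silenced
        x = steady_state(net).x
        hubs = select_hubs(net, x, k=1, expr_min=0.88)
        assert hubs.gene_ids == (0,)  # gene 1 has degree 1 but low expression
        with pytest.raises(ValueError, match="lower expr_min"):
            select_hubs(net, x, k=3, expr_min=0.88)

    def test_degree_ties_break_by_expression_then_index(self):
        W = np.zeros((4, 4))
        W[2, 0] = W[3, 0] = 1.0  # genes 0 and 1 tied at out-degree 2
        W[2, 1] = W[3, 1] = 1.0
        net = make_network(W, bias=[3.0, 6.0, 0.0, 0.0])  # gene 1 higher expr
        x = steady_state(net).x
        hubs = select_hubs(net, x, k=1, expr_min=0.88)
        assert hubs.gene_ids == (1,)

    def test_k_zero_empty(self, star_network):
        x = steady_state(star_network).x
        assert len(select_hubs(star_network, x, k=0)) == 0


class TestPerturbations:
    def test_knock_out_clamps_row_and_expression(self, star_network):
        x = steady_state(star_network).x
        net2, x2 = knock_out(star_network, x, 0)
        assert net2.W[0].nnz == 0
        assert x2[0] == 0.0

    def test_knock_out_without_targets_changes_nothing_else(self, star_network):
        x = steady_state(star_network).x
        _, x2 = knock_out(star_network, x, 6)  # isolated gene
        assert x2[6] == 0.0
        assert np.allclose(np.delete(x2, 6), np.delete(x, 6), atol=1e-6)

    def test_chain_knock_out_propagates_downstream(self, chain_network):
        x = steady_state(chain_network).x
        _, x2 = knock_out(chain_network, x, 0)
        assert x2[1] < x[1] - 0.05
        assert x2[2] < x[2] - 0.05

    def test_knock_down_halves_row_exactly(self, star_network):
        x = steady_state(star_network).x
        net2, _ = knock_down(star_network, x, 0)
        assert np.allclose(
            net2.W[0].toarray(), 0.5 * star_network.W[0].toarray(), rtol=1e-12
        )

    def test_knock_down_halves_isolated_unregulated_gene(self, star_network):
        x = steady_state(star_network).x
        _, x2 = knock_down(star_network, x, 6)
        assert np.isclose(x2[6], 0.5 * x[6], atol=1e-6)
        assert np.allclose(np.delete(x2, 6), np.delete(x, 6), atol=1e-6)

    def test_knock_down_weaker_than_knock_out(self, chain_network):
        x = steady_state(chain_network).x
        _, x_ko = knock_out(chain_network, x, 0)
        _, x_kd = knock_down(chain_network, x, 0)
        for g in (1, 2):
            assert abs(x_kd[g] - x[g]) <= abs(x_ko[g] - x[g]) + 1e-9


class TestAssignment:
    def test_equal_thirds_of_subset_sizes(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=6, expr_min=-1.0)
        plan = assign_perturbations(300, hubs, seed=0)
        sizes = [len(a) for a in plan.assignments]
        assert sorted(np.bincount(sizes)[4:7].tolist()) == [100, 100, 100]

    def test_per_hub_ko_kd_split(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=6, expr_min=-1.0)
        plan = assign_perturbations(300, hubs, seed=1)
        for hub in hubs.gene_ids:
            kinds = [a[hub] for a in plan.assignments if hub in a]
            n_ko = sum(1 for k in kinds if k == KO)
            assert n_ko == int(len(kinds) / 3)  # exact floor, remainder to KD

    def test_empty_and_invalid(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=6, expr_min=-1.0)
        assert assign_perturbations(0, hubs, seed=0).assignments == []
        small = select_hubs(star_network, x, k=2, expr_min=-1.0)
        with pytest.raises(ValueError):
            assign_perturbations(10, small, seed=0)

    def test_only_hubs_appear(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=6, expr_min=-1.0)
        plan = assign_perturbations(50, hubs, seed=2)
        for a in plan.assignments:
            assert set(a) <= set(hubs.gene_ids)


class TestTruth:
    def test_infinite_epsilon_empty(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=1, expr_min=0.88)
        truth = derive_truth(star_network, x, hubs, epsilon=np.inf)
        assert truth.gene_ids == frozenset()

    def test_threshold_separates_strong_from_weak_targets(self, star_network):
        x = steady_state(star_network).x
        hubs = select_hubs(star_network, x, k=1, expr_min=0.88)
        assert hubs.gene_ids == (0,)
        truth = derive_truth(star_network, x, hubs, epsilon=0.05)
        # exhaustive oracle: recompute each gene's change under KO and KD
        _, x_ko = knock_out(star_network, x, 0)
        _, x_kd = knock_down(star_network, x, 0)
        expected = {
            g
            for g in hub_reachable_genes(star_network, hubs)
            if max(abs(x_ko[g] - x[g]), abs(x_kd[g] - x[g])) > 0.05
        }
        assert truth.gene_ids == frozenset(expected)
        assert 0 in truth.gene_ids  # the hub itself
        assert 1 in truth.gene_ids  # strongly regulated target
        assert 5 not in truth.gene_ids  # weakly regulated target

    def test_truth_confined_to_reachable_set(self, small_random_network):
        net = small_random_network
        x = steady_state(net).x
        hubs = select_hubs(net, x, k=2, expr_min=-1.0)
        truth = derive_truth(net, x, hubs, epsilon=0.001)
        reach = hub_reachable_genes(net, hubs)
        assert truth.gene_ids <= reach
        # block separation: background genes never enter the truth set
        assert all(g < len(net.evolvable_idx) for g in truth.gene_ids)


class TestCohorts:
    def test_cohort_assembly_and_block_separation(self, small_random_network):
        from grnbench.evolution import EvolutionConfig, evolve
        from grnbench.disease_model import PerturbationPlan

        pop = evolve(
            small_random_network,
            EvolutionConfig(M=12, generations=2, seed=3, n_probe_mutants=150),
        )
        x = steady_state(small_random_network).x
        hubs = select_hubs(small_random_network, x, k=2, expr_min=-1.0)
        plan = assign_perturbations(
            6, hubs, seed=1, subset_sizes=(1, 2), ko_fraction=1 / 3
        )
        healthy, diseased = build_cohorts(pop, plan, 6, 6, seed=0)
        assert healthy.shape == (120, 6)
        assert diseased.shape == (120, 6)
        bg = small_random_network.background_idx()
        # background genes identical across groups before noise
        assert np.allclose(
            healthy[bg].mean(axis=1), diseased[bg].mean(axis=1), atol=1e-6
        )

        # empty plan: diseased columns equal those subjects' unperturbed states
        empty_plan = PerturbationPlan(assignments=[{} for _ in range(6)])
        _, d2 = build_cohorts(pop, empty_plan, 6, 6, seed=0)
        order = np.random.default_rng(0).permutation(pop.size)
        expected = np.column_stack(
            [pop.individuals[int(i)].phenotype for i in order[6:12]]
        )
        assert np.allclose(d2, expected, atol=1e-9)

    def test_capacity_validation(self, small_random_network):
        from grnbench.evolution import EvolutionConfig, evolve
        from grnbench.disease_model import PerturbationPlan

        pop = evolve(
            small_random_network,
            EvolutionConfig(M=4, generations=0, seed=3, n_probe_mutants=150),
        )
        plan = PerturbationPlan(assignments=[{} for _ in range(3)])
        with pytest.raises(ValueError):
            build_cohorts(pop, plan, 3, 3, seed=0)
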