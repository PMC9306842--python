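from __future__ import annotations

import math

import numpy as np
import pytest

from gmycsampler import SimulationConfig, simulate_truth_set
from gmycsampler.data_io import (
    BranchingEvent,
    BranchingSchedule,
    UltrametricTree,
    branching_events,
)
from gmycsampler.gmyc_model import (
    GmycConfig,
    GmycParams,
    LikelihoodError,
    SpeciesPartition,
    entity_counts,
    fit_null,
    fit_single_threshold,
    gmyc_log_likelihood,
    likelihood_ratio_test,
    node_support,
    profile_lambdas,
    single_class_rate,
    threshold_partition,
)

from oracles import brute_force_best_logL, naive_log_likelihood, naive_null_grid


class TestThresholdPartition:
    def test_above_root_one_species(self, three_tip_tree):
        part = threshold_partition(three_tip_tree, three_tip_tree.depth)
        assert part.n_species == 1
        assert part.species[0] == {"a", "b", "c"}

    def test_below_all_nodes_all_singletons(self, three_tip_tree):
        part = threshold_partition(three_tip_tree, 0.5)
        assert part.n_species == 3
        assert all(len(s) == 1 for s in part.species)

    def test_fixture_partition(self, fixture16):
        truth, imposed = fixture16
        from gmycsampler.synthesizer import FIXTURE_THRESHOLD

        assert threshold_partition(truth.tree, FIXTURE_THRESHOLD) == imposed
        assert imposed.n_species == 6

    def test_canonical_order_and_ids(self, fixture16):
        _, imposed = fixture16
        mins = [min(s) for s in imposed.species]
        assert mins == sorted(mins)
        assert imposed.ids == (1, 2, 3, 4, 5, 6)


class TestRates:
    def test_coalescent_three_lineages(self):
        assert single_class_rate(3, 1.0, 1.0, kind="coalescent") == 6.0

    def test_exponent_zero(self):
        assert single_class_rate(7, 0.5, 0.0, kind="coalescent") == 0.5

    def test_diversification_two(self):
        assert single_class_rate(2, 1.0, 1.0, kind="diversification") == 2.0

    def test_single_lineage_cannot_coalesce(self):
        assert single_class_rate(1, 5.0, 2.0, kind="coalescent") == 0.0


class TestLogLikelihood:
    def test_single_interval_closed_form(self):
        tree = UltrametricTree.from_newick("(a:0.5,b:0.5);")
        schedule = branching_events(tree, 0.2)
        params = GmycParams(1.0, 1.0, 1.0, 1.0, 0.2)
        assert gmyc_log_likelihood(schedule, params) == pytest.approx(
            math.log(2) - 1.0
        )

    def test_zero_coalescent_rate_is_minus_inf(self, three_tip_tree):
        schedule = branching_events(three_tip_tree, 1.5)
        params = GmycParams(1.0, 0.0, 1.0, 1.0, 1.5)
        assert gmyc_log_likelihood(schedule, params) == -math.inf

    def test_unclassified_schedule_rejected(self, three_tip_tree):
        schedule = branching_events(three_tip_tree, None)
        with pytest.raises(LikelihoodError):
            gmyc_log_likelihood(schedule, GmycParams(1, 1, 1, 1, 1))

    def test_fixture_matches_straight_line_oracle(self, fixture16):
        truth, _ = fixture16
        for T in (0.4, 1.0, 2.2, truth.tree.depth):
            schedule = branching_events(truth.tree, T)
            for params in (
                GmycParams(1.0, 2.0, 1.0, 1.0, T),
                GmycParams(0.3, 5.0, 0.0, 2.0, T),
                GmycParams(2.0, 0.7, 1.7, 0.3, T),
            ):
                assert gmyc_log_likelihood(schedule, params) == pytest.approx(
                    naive_log_likelihood(
                        schedule,
                        params.lambda_div,
                        params.lambda_coal,
                        params.p_div,
                        params.p_coal,
                    ),
                    rel=1e-12,
                )


class TestProfileLambdas:
    def test_rate_is_events_over_exposure(self, three_tip_tree):
        # T=1.5: one diversification event (exposure k^1*x summed) and one
        # coalescent event.
        schedule = branching_events(three_tip_tree, 1.5)
        lam_d, lam_c, logL = profile_lambdas(schedule, 1.0, 1.0)
        exp_div = sum(e.k * e.waiting_time for e in schedule.events)
        exp_coal = sum(
            sum(n * (n - 1) for n in e.coal_counts) * e.waiting_time
            for e in schedule.events
        )
        assert lam_d == pytest.approx(1 / exp_div)
        assert lam_c == pytest.approx(1 / exp_coal)

    def test_profile_beats_perturbed_lambdas(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            cfg = SimulationConfig(
                n_species=3 + seed % 4,
                samples_per_species=2 + seed % 3,
                coalescent_scale=0.05,
                seed=seed,
            )
            tree = simulate_truth_set(cfg).tree
            T = float(rng.uniform(0.1, 0.9)) * tree.depth
            schedule = branching_events(tree, T)
            p_d, p_c = float(rng.uniform(0, 3)), float(rng.uniform(0, 3))
            lam_d, lam_c, logL = profile_lambdas(schedule, p_d, p_c)
            for factor in (0.9, 1.1):
                perturbed = naive_log_likelihood(
                    schedule,
                    lam_d * factor if lam_d else 1e-3,
                    lam_c * factor if lam_c else 1e-3,
                    p_d,
                    p_c,
                )
                assert logL >= perturbed - 1e-9

    def test_zero_event_class_gets_zero_rate(self, three_tip_tree):
        schedule = branching_events(three_tip_tree, three_tip_tree.depth)
        lam_d, lam_c, logL = profile_lambdas(schedule, 1.0, 1.0)
        assert lam_d == 0.0
        assert lam_c > 0
        assert math.isfinite(logL)

    def test_zero_exposure_with_events_raises(self):
        events = (
            BranchingEvent(
                height=1.0,
                waiting_time=0.0,
                n_lineages=2,
                k=2,
                coal_counts=(),
                is_diversification=True,
            ),
        )
        schedule = BranchingSchedule(
            events=events, depth=1.0, n_tips=2, threshold=0.5
        )
        with pytest.raises(LikelihoodError, match="exposure"):
            profile_lambdas(schedule, 1.0, 1.0)


class TestFitNull:
    def test_closed_form_at_p_zero(self, three_tip_tree):
        schedule = branching_events(three_tip_tree, None)
        lam0, p0, _ = fit_null(schedule, p0=0.0)
        x = [e.waiting_time for e in schedule.events]
        assert p0 == 0.0
        assert lam0 == pytest.approx(2 / (x[0] + x[1]))

    def test_null_equals_all_coalescent_classification(self, fixture16):
        truth, _ = fixture16
        tree = truth.tree
        lam0, p0, null_logL = fit_null(branching_events(tree, None))
        schedule = branching_events(tree, tree.depth)
        params = GmycParams(0.0, lam0, 0.0, p0, tree.depth)
        assert gmyc_log_likelihood(schedule, params) == pytest.approx(
            null_logL, rel=1e-9
        )

    def test_beats_lambda_p_grid(self):
        cfg = SimulationConfig(
            n_species=20, samples_per_species=1, coalescent_scale=0.05, seed=5
        )
        tree = simulate_truth_set(cfg).tree
        schedule = branching_events(tree, None)
        lam0, p0, logL = fit_null(schedule)
        grid_best = naive_null_grid(
            schedule,
            lam_grid=np.linspace(0.05, 20 * lam0, 50),
            p_grid=np.linspace(0.0, 5.0, 50),
        )
        assert logL >= grid_best - 1e-6


class TestFitSingleThreshold:
    def test_recovers_five_species(self):
        cfg = SimulationConfig(
            n_species=5,
            samples_per_species=4,
            coalescent_scale=0.002,
            seed=1,
            min_species_separation=20.0,
        )
        truth = simulate_truth_set(cfg)
        fit = fit_single_threshold(truth.tree)
        assert fit.n_entities == 5
        assert fit.partition == truth.true_partition

    def test_nesting_on_single_class_tree(self):
        # All heights from one coalescent process: LR should be modest and
        # logL >= null always.
        cfg = SimulationConfig(
            n_species=1, samples_per_species=12, coalescent_scale=0.3, seed=9
        )
        truth = simulate_truth_set(cfg)
        fit = fit_single_threshold(truth.tree)
        assert fit.logL >= fit.null_logL - 1e-9
        assert fit.LR >= 0

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle_small_trees(self, seed):
        cfg = SimulationConfig(
            n_species=2 + seed % 3,
            samples_per_species=[2, 3, 1, 2][: 2 + seed % 3],
            coalescent_scale=0.1,
            seed=seed,
        )
        tree = simulate_truth_set(cfg).tree
        assert tree.n_tips <= 8
        fit = fit_single_threshold(tree)
        oracle_logL, _ = brute_force_best_logL(tree)
        assert fit.logL == pytest.approx(oracle_logL, abs=1e-4)
        assert fit.logL >= fit.null_logL - 1e-9

    def test_determinism(self, fixture16):
        truth, _ = fixture16
        f1 = fit_single_threshold(truth.tree)
        f2 = fit_single_threshold(truth.tree)
        assert f1 == f2

    def test_counts_consistent(self, fixture16):
        truth, _ = fixture16
        fit = fit_single_threshold(truth.tree)
        assert fit.n_entities == fit.n_clusters + fit.n_singletons
        assert fit.n_entities == fit.partition.n_species
        assert 0.0 <= fit.p_value <= 1.0

    def test_needs_three_tips(self):
        tree = UltrametricTree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="3 tips"):
            fit_single_threshold(tree)


class TestLikelihoodRatioTest:
    def test_zero_lr_gives_p_one(self):
        LR, p = likelihood_ratio_test(10.0, 10.0, df=3)
        assert LR == 0.0
        assert p == 1.0

    def test_chi2_quantile_df3(self):
        LR, p = likelihood_ratio_test(10.0, 10.0 - 7.815 / 2, df=3)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_chi2_quantile_df2(self):
        LR, p = likelihood_ratio_test(10.0, 10.0 - 5.991 / 2, df=2)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_negative_lr_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(5.0, 10.0, df=3)


class TestEntityCounts:
    def test_fixture_counts(self, fixture16):
        _, imposed = fixture16
        assert entity_counts(imposed) == (6, 5, 1)

    def test_all_singletons(self):
        part = SpeciesPartition(tuple(frozenset([f"t{i}"]) for i in range(5)))
        assert entity_counts(part) == (5, 0, 5)

    def test_one_species(self):
        part = SpeciesPartition((frozenset({"a", "b", "c"}),))
        assert entity_counts(part) == (1, 1, 0)


class TestNodeSupport:
    def test_equal_logL_two_candidates(self, three_tip_tree):
        # T=1.5 defines species {a,b}; T=depth defines {a,b,c}.
        profile = [(1.5, -5.0), (2.0, -5.0)]
        support = node_support(three_tip_tree, profile)
        assert support[frozenset({"a", "b"})] == pytest.approx(0.5)
        assert support[frozenset({"a", "b", "c"})] == pytest.approx(0.5)

    def test_node_in_every_model_has_support_one(self, three_tip_tree):
        profile = [(1.2, -3.0), (1.8, -1.0)]
        support = node_support(three_tip_tree, profile)
        assert support[frozenset({"a", "b"})] == pytest.approx(1.0)

    def test_supports_in_unit_interval(self, fixture16):
        truth, _ = fixture16
        fit = fit_single_threshold(truth.tree)
        support = node_support(truth.tree, fit.threshold_profile)
        assert support
        for value in support.values():
            assert 0.0 <= value <= 1.0 + 1e-12


def test_boundary_entity_counts_on_random_trees():
    for seed in range(10):
        cfg = SimulationConfig(
            n_species=3, samples_per_species=3, coalescent_scale=0.05, seed=seed
        )
        tree = simulate_truth_set(cfg).tree
        assert threshold_partition(tree, tree.depth).n_species == 1
        lowest = min(n.height for n in tree.internal_nodes())
        assert threshold_partition(tree, lowest / 2).n_species == tree.n_tips
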