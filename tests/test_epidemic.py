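"""Epidemic thresholds, SIR/SIS dynamics, equilibrium protocol, calibration."""

import math

import networkx as nx
import numpy as np
import pytest

from spreadnet import (
    CalibrationError,
    DegreeMoments,
    EquilibriumPolicy,
    FixtureSpec,
    NoEquilibriumError,
    SIRConfig,
    SISConfig,
    calibrate_sir,
    calibrate_sis,
    degree_moments,
    detect_equilibrium,
    make_fixture,
    simulate_sir,
    simulate_sir_batch,
    simulate_sis,
    sir_ground_truth,
    sir_threshold,
    sis_ground_truth,
    sis_threshold,
)

from conftest import bond_percolation_mean_outbreak


class TestThresholds:
    def test_sir_regular_graph_closed_form(self):
        # k-regular: T^c = k/(k^2 - k) = 1/(k-1).
        assert sir_threshold(DegreeMoments(5.0, 25.0)) == pytest.approx(0.25)

    def test_sir_star_moments(self):
        assert sir_threshold(DegreeMoments(1.6, 4.0)) == pytest.approx(1.6 / 2.4)

    def test_sis_regular_graph_closed_form(self):
        assert sis_threshold(DegreeMoments(5.0, 25.0)) == pytest.approx(0.2)

    def test_sir_undefined_on_perfect_matching(self):
        # 1-regular graph: <k^2> = <k> = 1, denominator vanishes.
        moments = degree_moments(nx.Graph([(0, 1), (2, 3)]))
        with pytest.raises(ValueError):
            sir_threshold(moments)

    def test_sis_undefined_on_edgeless_graph(self):
        graph = nx.empty_graph(3)
        with pytest.raises(ValueError):
            sis_threshold(degree_moments(graph))


class TestSimulateSIR:
    def test_beta_zero_infects_only_the_seed(self, graph_zoo):
        for graph in graph_zoo.values():
            for v in graph.nodes:
                assert simulate_sir(graph, SIRConfig(beta=0.0), v) == 1

    def test_beta_one_gives_connected_component_size(self, graph_zoo):
        config = SIRConfig(beta=1.0, gamma=1.0, rng_seed=1)
        for graph in graph_zoo.values():
            for v in graph.nodes:
                expected = len(nx.node_connected_component(graph, v))
                assert simulate_sir(graph, config, v) == expected

    def test_missing_seed_node_errors(self):
        with pytest.raises(ValueError):
            simulate_sir(nx.path_graph(3), SIRConfig(beta=0.5), "ghost")

    def test_matches_bond_percolation_enumeration(self, graph_zoo):
        """With gamma=1, E[M_i] equals the exact bond-percolation value."""
        graph = graph_zoo["k4_pendant"]  # 5 nodes, 7 edges -> 128 subsets
        n_runs = 20_000
        for beta in (0.3, 0.6):
            for seed_node in (0, "leaf"):
                outbreaks = simulate_sir_batch(
                    graph, SIRConfig(beta=beta, rng_seed=42), seed_node, n_runs
                )
                exact = bond_percolation_mean_outbreak(graph, seed_node, beta)
                se = outbreaks.std(ddof=1) / math.sqrt(n_runs)
                assert abs(outbreaks.mean() - exact) < 3 * se + 1e-9

    def test_mean_outbreak_monotone_in_beta(self, graph_zoo):
        graph = graph_zoo["ba30"]
        means = [
            simulate_sir_batch(graph, SIRConfig(beta=b, rng_seed=5), 0, 3000).mean()
            for b in (0.1, 0.3, 0.6)
        ]
        assert means[0] < means[1] < means[2]

    def test_slow_recovery_still_terminates(self):
        # gamma < 1: nodes stay infectious for a geometric number of periods.
        outbreak = simulate_sir(
            nx.path_graph(10), SIRConfig(beta=0.4, gamma=0.3, rng_seed=2), 0
        )
        assert 1 <= outbreak <= 10


class TestSIRGroundTruth:
    def test_beta_zero_all_ones(self, graph_zoo):
        truth = sir_ground_truth(
            graph_zoo["triangle"], SIRConfig(beta=0.0, n_simulations=5)
        )
        assert set(truth.values.values()) == {1.0}
        assert set(truth.ranking.ordered_nodes) == set(graph_zoo["triangle"].nodes)

    def test_beta_one_on_two_components_gives_component_sizes(self, graph_zoo):
        graph = graph_zoo["two_components"]  # K4 union K2
        truth = sir_ground_truth(graph, SIRConfig(beta=1.0, n_simulations=3))
        sizes = {v: len(nx.node_connected_component(graph, v)) for v in graph.nodes}
        assert truth.values == {v: float(s) for v, s in sizes.items()}

    def test_monte_carlo_error_shrinks_with_simulations(self):
        graph, _ = make_fixture(FixtureSpec("barabasi_albert", {"n": 50, "m": 2}, 9))
        beta = 1.5 * sir_threshold(degree_moments(graph))

        def spread(n_simulations, seed_a, seed_b):
            a = sir_ground_truth(
                graph, SIRConfig(beta=beta, n_simulations=n_simulations, rng_seed=seed_a)
            )
            b = sir_ground_truth(
                graph, SIRConfig(beta=beta, n_simulations=n_simulations, rng_seed=seed_b)
            )
            return np.mean(
                [abs(a.values[v] - b.values[v]) for v in graph.nodes]
            )

        assert spread(400, 1, 2) < spread(10, 3, 4)

    def test_reproducible_under_fixed_seed(self, graph_zoo):
        config = SIRConfig(beta=0.4, n_simulations=20, rng_seed=11)
        first = sir_ground_truth(graph_zoo["ba30"], config)
        second = sir_ground_truth(graph_zoo["ba30"], config)
        assert first.values == second.values
        assert first.ranking.ordered_nodes == second.ranking.ordered_nodes


class TestCalibrateSIR:
    def test_dense_fixture_returns_critical_threshold_at_first_grid_point(self):
        # On K10 any outbreak satisfies the 1%-of-graph criterion, so the
        # scan stops at p=1 and returns T^c itself.
        graph = nx.complete_graph(10)
        t_star = calibrate_sir(
            graph, SIRConfig(beta=0.0, n_simulations=10, rng_seed=0)
        )
        assert t_star == pytest.approx(sir_threshold(degree_moments(graph)))

    def test_degenerate_grid_never_passes(self):
        graph, _ = make_fixture(FixtureSpec("barabasi_albert", {"n": 120, "m": 2}, 1))
        with pytest.raises(CalibrationError):
            # p=0 forces beta=0: every outbreak is 1, never > 1% of 120 nodes.
            calibrate_sir(
                graph, SIRConfig(beta=0.0, n_simulations=5, rng_seed=0), p_grid=[0.0]
            )

    def test_reproducible_and_monotone_in_criterion(self):
        graph, _ = make_fixture(FixtureSpec("barabasi_albert", {"n": 100, "m": 3}, 21))
        base = SIRConfig(beta=0.0, n_simulations=50, rng_seed=6)
        t_star_a = calibrate_sir(graph, base)
        t_star_b = calibrate_sir(graph, base)
        assert t_star_a == t_star_b
        stricter = calibrate_sir(graph, base, outbreak_fraction=0.05)
        assert stricter >= t_star_a


class TestDetectEquilibrium:
    POLICY = EquilibriumPolicy(rest_periods=5, window_periods=4, tolerance=1e-9)

    def test_constant_trajectory_declared_at_rest_plus_window(self):
        trajectory = [0.4] * 50
        reached, start = detect_equilibrium(trajectory, self.POLICY)
        assert reached and start == 9  # rest 5 + window 4, rise at t=0

    def test_strictly_decreasing_never_declared(self):
        trajectory = [1.0 - 0.01 * t for t in range(60)]
        assert detect_equilibrium(trajectory, self.POLICY) == (False, None)

    def test_sawtooth_declared_when_window_mean_vanishes(self):
        # 0.5, 0.6, 0.5, ... : rise at t=0, window start 5, first check at
        # t=9 gives (I(9)-I(5))/4 = 0.
        trajectory = [0.5 + 0.1 * (t % 2) for t in range(20)]
        reached, start = detect_equilibrium(trajectory, self.POLICY)
        assert reached and start == 9

    def test_decay_then_plateau_waits_for_the_rise(self):
        trajectory = [0.5 - 0.05 * t for t in range(6)] + [0.2] * 30
        reached, start = detect_equilibrium(trajectory, self.POLICY)
        # Decay ends at index 6; first non-negative delta at t=6 (0.2 -> 0.2),
        # so equilibrium at 6 + rest 5 + window 4.
        assert reached and start == 15


class TestSimulateSIS:
    def test_no_transmission_dies_out_with_zero_persistence(self):
        result = simulate_sis(
            nx.complete_graph(10),
            SISConfig(nu=0.0, delta=0.5, rng_seed=0),
        )
        assert result.extinct
        assert set(result.persistence.values()) == {0.0}
        assert result.density_trajectory[-1] == 0.0

    def test_near_zero_recovery_saturates_density(self):
        result = simulate_sis(
            nx.complete_graph(20),
            SISConfig(nu=0.5, delta=0.01, rng_seed=1),
        )
        assert result.equilibrium_density > 0.9

    def test_complete_graph_matches_mean_field_fixed_point(self):
        """K50 equilibrium density ~ 1 - delta/(nu (n-1)) for small nu."""
        n, nu, delta = 50, 0.004, 0.08
        expected = 1.0 - delta / (nu * (n - 1))
        densities = []
        for seed in range(5):
            result = simulate_sis(
                nx.complete_graph(n), SISConfig(nu=nu, delta=delta, rng_seed=seed)
            )
            densities.append(result.equilibrium_density)
        assert np.mean(densities) == pytest.approx(expected, abs=0.05)

    def test_max_periods_exceeded_raises_no_equilibrium(self):
        policy = EquilibriumPolicy(rest_periods=100, window_periods=100, max_periods=50)
        with pytest.raises(NoEquilibriumError):
            simulate_sis(
                nx.complete_graph(20),
                SISConfig(nu=0.2, delta=0.5, rng_seed=0, equilibrium=policy),
            )

    def test_density_trajectory_is_density_valued(self):
        result = simulate_sis(nx.complete_graph(15), SISConfig(nu=0.3, rng_seed=3))
        trajectory = np.array(result.density_trajectory)
        assert ((0.0 <= trajectory) & (trajectory <= 1.0)).all()
        assert trajectory[0] == pytest.approx(0.2)  # 20% initially infected


class TestCalibrateSIS:
    def test_first_passing_grid_point_returned_for_both(self):
        # K15 well above threshold: a single-point grid that passes both
        # criteria must yield lambda_hat == lambda_star == p * lambda^c.
        graph = nx.complete_graph(15)
        lambda_critical = sis_threshold(degree_moments(graph))
        lambda_hat, lambda_star = calibrate_sis(
            graph, SISConfig(nu=0.1, rng_seed=0), p_grid=[3.0], n_runs=3
        )
        assert lambda_hat == pytest.approx(3.0 * lambda_critical)
        assert lambda_star == lambda_hat

    def test_scan_returns_grid_multiples_of_threshold(self):
        graph = nx.complete_graph(15)
        lambda_critical = sis_threshold(degree_moments(graph))
        lambda_hat, lambda_star = calibrate_sis(
            graph, SISConfig(nu=0.1, rng_seed=0), n_runs=3
        )
        grid = [round(1.0 + 0.1 * i, 10) for i in range(21)]
        assert min(abs(lambda_hat / lambda_critical - p) for p in grid) < 1e-9
        assert min(abs(lambda_star / lambda_critical - p) for p in grid) < 1e-9
        assert lambda_star >= lambda_hat

    def test_grid_exhaustion_raises(self):
        graph = nx.complete_graph(10)
        with pytest.raises(CalibrationError):
            calibrate_sis(
                graph, SISConfig(nu=0.1, rng_seed=0), p_grid=[1e-6], n_runs=2
            )

    def test_lambda_star_never_below_lambda_hat(self, graph_zoo):
        lambda_hat, lambda_star = calibrate_sis(
            graph_zoo["ba30"], SISConfig(nu=0.1, rng_seed=4), n_runs=3
        )
        assert lambda_star >= lambda_hat


class TestSISGroundTruth:
    def test_no_transmission_gives_all_zero_values(self):
        truth = sis_ground_truth(
            nx.complete_graph(8), SISConfig(nu=0.0, n_simulations=3, rng_seed=0)
        )
        assert set(truth.values.values()) == {0.0}

    def test_values_are_frequencies(self, graph_zoo):
        truth = sis_ground_truth(
            graph_zoo["ba30"], SISConfig(nu=0.3, n_simulations=5, rng_seed=2)
        )
        assert all(0.0 <= x <= 1.0 for x in truth.values.values())

    def test_dense_component_outranks_sparse_component(self):
        """Nodes of the supercritical component persist; the subcritical die."""
        graph, _ = make_fixture(
            FixtureSpec(
                "union",
                {
                    "components": [
                        FixtureSpec("complete", {"n": 20}),
                        FixtureSpec("complete", {"n": 3}),
                    ]
                },
            )
        )
        # lambda = 0.2: above K20's threshold 1/19, below K3's threshold 1/2.
        truth = sis_ground_truth(
            graph, SISConfig(nu=0.04, delta=0.2, n_simulations=10, rng_seed=5)
        )
        k20_mean = np.mean([truth.values[v] for v in graph.nodes if v.startswith("c0")])
        k3_mean = np.mean([truth.values[v] for v in graph.nodes if v.startswith("c1")])
        assert k20_mean > 0.3 > k3_mean

    def test_persistence_profile_invariant_under_relabeling(self):
        """Structurally equivalent nodes get equivalent persistence."""
        star = nx.star_graph(6)
        relabeled = nx.relabel_nodes(star, {v: f"node{v}" for v in star.nodes})
        config = SISConfig(nu=0.9, delta=0.5, n_simulations=40)
        original = sis_ground_truth(star, config)
        renamed = sis_ground_truth(relabeled, config)
        assert original.values[0] == pytest.approx(
            renamed.values["node0"], abs=0.05
        )
        leaves_a = np.mean([original.values[v] for v in range(1, 7)])
        leaves_b = np.mean([renamed.values[f"node{v}"] for v in range(1, 7)])
        assert leaves_a == pytest.approx(leaves_b, abs=0.05)
        assert original.values[0] > leaves_a  # hub is infected more often
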