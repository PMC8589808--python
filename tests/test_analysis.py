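"""Equilibrium refinement, connection tests, itineraries and fold thresholds."""

import numpy as np
import pytest

from enact.analysis import test_connection as check_connection
from enact.analysis import (
    InvalidWalkError,
    Itinerary,
    NoEquilibriumError,
    _one_active_equilibrium_exists,
    detect_bottlenecks,
    double_activation_events,
    dwell_filtered_events,
    estimate_period,
    execute_walk,
    itinerary,
    lemma2_positions,
    refine_equilibrium,
    snic_threshold_cycle,
    transition_statistics,
    wp_sn_closed_form,
    wp_sn_numeric,
    wp_sn_prime,
)
from enact.construct import (
    ActivationSpec,
    activation,
    activation_inverse,
    build_weight_matrix,
    default_smooth_params,
    predicted_equilibrium,
)
from enact.dynamics import simulate_ode
from enact.graphs import DiGraph


class TestRefine:
    def test_piecewise_recipe_point_is_exact(self, three_cycle, params04, piecewise04):
        W = build_weight_matrix(three_cycle, params04)
        xi1 = predicted_equilibrium(three_cycle, params04, 1).state
        eq = refine_equilibrium(W, piecewise04, xi1)
        assert np.array_equal(eq.state, xi1)
        assert eq.residual == 0.0
        assert np.allclose(eq.eigenvalues, -1.0)  # saturated Jacobian is -I
        assert eq.stable

    def test_smooth_point_close_to_prediction(self, three_cycle, params04, smooth04):
        W = build_weight_matrix(three_cycle, params04)
        guess = np.array([1.0, 0.3, -0.7])
        eq = refine_equilibrium(W, smooth04, guess)
        assert eq.stable
        assert eq.residual <= 1e-10
        assert np.max(np.abs(eq.state - guess)) < 0.05  # O(eps) shift only

    def test_fold_detected_past_threshold(self, two_cell):
        """Past the fold the designed sink is gone: refinement either fails or
        lands on a different equilibrium, and the existence predicate is False."""
        base = default_smooth_params()
        spec = ActivationSpec.from_params(base, "smooth")
        guess = np.array([1.0, 0.3])
        for wp, expected in [(0.30, True), (0.31, False)]:
            W = build_weight_matrix(two_cell, base.replace(w_p=wp))
            assert _one_active_equilibrium_exists(W, spec, guess) is expected
        W31 = build_weight_matrix(two_cell, base.replace(w_p=0.31))
        try:
            eq = refine_equilibrium(W31, spec, guess)
            assert np.max(np.abs(eq.state - guess)) > 0.2
        except NoEquilibriumError:
            pass

    def test_nonfinite_guess_rejected(self, three_cycle, params04, smooth04):
        W = build_weight_matrix(three_cycle, params04)
        with pytest.raises(ValueError):
            refine_equilibrium(W, smooth04, np.array([np.nan, 0, 0]))


class TestConnections:
    def test_edge_kick_connects(self, three_cycle, params04, piecewise04):
        out = check_connection(three_cycle, params04, piecewise04, 1, 2, delta=0.4)
        assert out.classification == "connected"
        assert out.destination == 2
        assert out.transit_time is not None and out.transit_time > 0

    def test_non_edge_kick_returns(self, three_cycle, params04, piecewise04):
        out = check_connection(three_cycle, params04, piecewise04, 1, 3, delta=0.4)
        assert out.classification == "returned"
        assert out.destination == 1

    def test_zero_kick_stays(self, three_cycle, params04, piecewise04):
        out = check_connection(three_cycle, params04, piecewise04, 1, 2, delta=0.0)
        assert out.classification == "returned"
        assert out.transit_time == 0.0

    def test_isolated_cell_kick_returns(self, params04, piecewise04):
        g = DiGraph.from_edges(4, [(1, 2), (2, 3), (3, 1)])
        out = check_connection(g, params04, piecewise04, 1, 4, delta=0.4)
        assert out.classification == "returned"


class TestItinerary:
    def test_constant_trajectory_single_event(self, three_cycle, params04, smooth04):
        W = build_weight_matrix(three_cycle, params04)
        xi1 = predicted_equilibrium(three_cycle, params04, 1).state
        traj = simulate_ode(W, smooth04, xi1, t_max=10)
        it = itinerary(traj, smooth04)
        assert it.events == [(0.0, frozenset({1}))]

    def test_spontaneous_cycle_is_periodic_in_order(self, three_cycle, smooth04):
        p = default_smooth_params().replace(w_p=0.305)
        W = build_weight_matrix(three_cycle, p)
        y0 = predicted_equilibrium(three_cycle, p, 1).state + np.array([0, 0.05, 0])
        traj = simulate_ode(W, smooth04, y0, t_max=300)
        singles = [
            next(iter(s))
            for _, s in dwell_filtered_events(itinerary(traj, smooth04), 1.0)
            if len(s) == 1
        ]
        assert set(singles) == {1, 2, 3}
        for a, b in zip(singles[:-1], singles[1:]):
            assert (b - a) % 3 == 1  # strict cyclic order 1 -> 2 -> 3 -> 1

    def test_hysteresis_levels_validated(self, three_cycle, params04, smooth04):
        W = build_weight_matrix(three_cycle, params04)
        traj = simulate_ode(W, smooth04, np.zeros(3), t_max=1)
        with pytest.raises(ValueError):
            itinerary(traj, smooth04, on_level=0.2, off_level=0.8)

    def test_dwell_filter_drops_chatter(self):
        ev = [
            (0.0, frozenset({1})),
            (10.0, frozenset({1, 2})),
            (10.5, frozenset({2})),
            (20.0, frozenset({3})),
        ]
        it = Itinerary(events=ev, hysteresis=(0.8, 0.2), t_end=30.0)
        kept = [s for _, s in dwell_filtered_events(it, 1.0)]
        assert kept == [frozenset({1}), frozenset({2}), frozenset({3})]


class TestThresholds:
    def test_closed_form_at_default_point(self):
        assert wp_sn_closed_form(0.05, 0.5, 1.0) == pytest.approx(0.3027, abs=5e-5)

    def test_closed_form_limit_is_theta(self):
        vals = [wp_sn_closed_form(e, 0.5, 1.0) for e in (0.01, 0.001, 0.0001)]
        gaps = [abs(v - 0.5) for v in vals]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.002

    def test_closed_form_warns_outside_hypothesis(self):
        with pytest.warns(UserWarning):
            wp_sn_closed_form(0.05, 1.5, 1.0)

    def test_numeric_fold_matches_asymptotics(self, smooth04):
        p = default_smooth_params()
        num = wp_sn_numeric(p, smooth04)
        assert num == pytest.approx(0.3027, abs=5e-4)

    def test_fold_error_scales_as_eps_cubed(self):
        p0 = default_smooth_params()
        for eps in (0.05, 0.025, 0.0125):
            p = p0.replace(eps=eps)
            spec = ActivationSpec.from_params(p, "smooth")
            diff = abs(wp_sn_numeric(p, spec) - wp_sn_closed_form(eps, p.theta, p.w_s))
            assert diff <= 2.0 * eps**3

    def test_extrema_precondition(self):
        p = default_smooth_params().replace(eps=0.3)  # w_s = 1 < 4 eps
        spec = ActivationSpec.from_params(p, "smooth")
        with pytest.raises(ValueError, match="4 eps"):
            wp_sn_numeric(p, spec)

    def test_snic_close_to_two_cell_fold(self, smooth04):
        p = default_smooth_params()
        snic = snic_threshold_cycle(p, smooth04)
        assert snic == pytest.approx(0.30287, abs=1e-4)
        assert abs(snic - wp_sn_numeric(p, smooth04)) < 2e-4

    def test_double_activation_fold_directions(self, smooth04):
        p = default_smooth_params()
        num = wp_sn_numeric(p, smooth04)
        base = wp_sn_prime(0.0, 0.0, p, smooth04)
        # at w_t = 0 the pair decouples into two copies of the two-cell fold;
        # the sheet idealisation differs from the full fold only by the
        # exponentially small saturation gap
        assert abs(base - num) < 5e-5
        assert wp_sn_prime(-0.05, 0.0, p, smooth04) > base
        assert wp_sn_prime(+0.05, 0.0, p, smooth04) < base
        # a boosted competing edge folds earlier by the boost
        assert wp_sn_prime(0.0, 0.002, p, smooth04) == pytest.approx(base - 0.002, abs=1e-9)


class TestLemma2:
    def test_symmetry_and_coalescence(self):
        p = default_smooth_params()
        lo, hi = lemma2_positions(1e-4, p)
        centre = p.eps / p.w_s
        assert lo + hi == pytest.approx(2 * centre)
        lo2, hi2 = lemma2_positions(1e-6, p)
        assert hi2 - lo2 < hi - lo  # coalesce toward eps/w_s as eta -> 0

    def test_warns_outside_hypothesis(self):
        p = default_smooth_params()
        with pytest.warns(UserWarning):
            lemma2_positions(p.eps, p)

    @pytest.mark.parametrize("eta", [1e-4, 3e-4, 1e-3])
    def test_newton_recovers_predicted_positions(self, eta, two_cell, smooth04):
        p = default_smooth_params()
        wp_fold = wp_sn_numeric(p, smooth04)
        lo, hi = lemma2_positions(eta, p)
        W = build_weight_matrix(two_cell, p.replace(w_p=wp_fold - eta))
        for j2 in (lo, hi):
            y_guess = np.array(
                [p.w_s + p.w_m * j2, float(activation_inverse(j2, smooth04))]
            )
            eq = refine_equilibrium(W, smooth04, y_guess)
            j2_refined = float(activation(eq.state[1], smooth04))
            assert abs(j2_refined - j2) < 5 * p.eps**2


class TestBottlenecks:
    def test_three_ghosts_per_period(self, three_cycle, smooth04):
        p = default_smooth_params().replace(w_p=0.305)
        W = build_weight_matrix(three_cycle, p)
        y0 = predicted_equilibrium(three_cycle, p, 1).state + np.array([0, 0.05, 0])
        traj = simulate_ode(W, smooth04, y0, t_max=300)
        period = estimate_period(itinerary(traj, smooth04))
        found = detect_bottlenecks(traj, W, smooth04)
        in_last_period = [t for t, _, _ in found if t >= 300 - period]
        assert len(in_last_period) == 3

    def test_rest_at_equilibrium_is_not_a_passage(self, three_cycle, params04, smooth04):
        W = build_weight_matrix(three_cycle, params04)
        from enact.analysis import equilibrium_candidates

        xi1 = equilibrium_candidates(three_cycle, params04, smooth04)[1].state
        traj = simulate_ode(W, smooth04, xi1, t_max=50)
        assert detect_bottlenecks(traj, W, smooth04) == []


class TestTransitionStatistics:
    def test_empty_input_gives_zeros(self):
        stats = transition_statistics([], [{3}, {4}, {3, 4}])
        assert all(v == 0 for v in stats["counts"].values())
        assert all(v == 0.0 for v in stats["ratios"].values())

    def test_counts_follow_source(self):
        ev = [
            (0.0, frozenset({2})),
            (10.0, frozenset({3})),
            (20.0, frozenset({2})),
            (30.0, frozenset({3, 4})),
            (40.0, frozenset({1})),
        ]
        it = Itinerary(events=ev, hysteresis=(0.8, 0.2), t_end=50.0)
        stats = transition_statistics([it], [{3}, {4}, {3, 4}], source={2})
        assert stats["counts"][frozenset({3})] == 1
        assert stats["counts"][frozenset({4})] == 0
        assert stats["counts"][frozenset({3, 4})] == 1
        assert stats["ratios"][frozenset({3})] == 0.5

    def test_double_activation_requires_non_adjacent_pair(self, kirk_silber):
        ev = [
            (0.0, frozenset({1})),
            (10.0, frozenset({1, 2})),  # edge pair: handover, not a state
            (20.0, frozenset({3, 4})),  # non-adjacent siblings: genuine
        ]
        it = Itinerary(events=ev, hysteresis=(0.8, 0.2), t_end=40.0)
        dbl = double_activation_events(it, kirk_silber, min_dwell=1.0)
        assert [s for _, s in dbl] == [frozenset({3, 4})]


class TestExecuteWalk:
    def test_three_cycle_walk(self, three_cycle, params04, piecewise04):
        _, ok = execute_walk(three_cycle, params04, piecewise04, [1, 2, 3, 1], amplitude=0.5)
        assert ok

    def test_branching_is_input_selected(self, kirk_silber, params04, smooth04):
        _, ok_a = execute_walk(kirk_silber, params04, smooth04, [1, 2, 4, 1], amplitude=0.5)
        _, ok_b = execute_walk(kirk_silber, params04, smooth04, [1, 2, 3, 1], amplitude=0.5)
        assert ok_a and ok_b

    def test_non_edge_walk_rejected_before_simulation(self, three_cycle, params04, piecewise04):
        with pytest.raises(InvalidWalkError):
            execute_walk(three_cycle, params04, piecewise04, [1, 3])
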