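"""Fractile schedule, monotone spline fit, marginal utility, Deming."""

import numpy as np
import pytest

from margutil import (Gamble, UtilityFunction, average_sessions,
                      build_fractile_schedule, certainty_equivalent,
                      deming_regression, expected_utility, fit_utility,
                      interval_marginal_utility, marginal_utility,
                      run_fractile, validate_out_of_sample)
from margutil.fractile import sample_validation_gambles


@pytest.fixture(scope="module")
def linear_u():
    return UtilityFunction.linear()


@pytest.fixture(scope="module")
def truth_fit(truth):
    """Noiseless fractile points from the ground truth, fitted."""
    sched = build_fractile_schedule(3)
    pts = run_fractile(lambda g, r: truth.certainty_equivalent(g), sched,
                       repeats=1, rng=0, domain=truth.domain)
    return pts, fit_utility(pts, domain=truth.domain)


class TestExpectedUtility:
    def test_full_range_gamble_has_half_utility(self, truth_fit):
        _, u = truth_fit
        g = Gamble.even(0.1, 1.2)
        assert expected_utility(g, u) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_gamble_returns_pointwise_utility(self, truth_fit):
        _, u = truth_fit
        assert expected_utility(Gamble.safe(0.7), u) == pytest.approx(u(0.7))

    def test_identity_utility_gives_task_evs(self, linear_u):
        evs = [expected_utility(g, lambda x: x)
               for g in (Gamble.even(0.1, 0.4), Gamble.even(0.5, 0.8),
                         Gamble.even(0.9, 1.2))]
        assert evs == pytest.approx([0.25, 0.65, 1.05])


class TestCertaintyEquivalent:
    def test_linear_utility_makes_ce_equal_ev(self, linear_u):
        g = Gamble.even(0.3, 0.9)
        assert certainty_equivalent(g, linear_u) == pytest.approx(
            g.expected_value, abs=1e-9)

    def test_convex_region_ce_above_ev(self, truth_fit):
        _, u = truth_fit
        g = Gamble.even(0.1, 0.4)
        assert certainty_equivalent(g, u) > g.expected_value

    def test_concave_region_ce_below_ev(self, truth_fit):
        _, u = truth_fit
        g = Gamble.even(0.9, 1.2)
        assert certainty_equivalent(g, u) < g.expected_value

    def test_roundtrip_u_of_ce_equals_eu(self, truth_fit):
        _, u = truth_fit
        for g in (Gamble.even(0.2, 0.9), Gamble.even(0.4, 1.1)):
            ce = certainty_equivalent(g, u)
            assert u(ce) == pytest.approx(expected_utility(g, u), abs=1e-9)


class TestSchedule:
    def test_root_is_the_full_range_bisection(self):
        sched = build_fractile_schedule(1, edge_refinement=False)
        assert [n.level for n in sched] == [0.5]

    def test_second_step_bisects_both_subintervals(self):
        sched = build_fractile_schedule(2, edge_refinement=False)
        assert sorted(n.level for n in sched) == [0.25, 0.5, 0.75]

    def test_three_upper_bisections_reach_fifteen_sixteenths(self):
        sched = build_fractile_schedule(3, edge_refinement=True)
        assert max(n.level for n in sched) == pytest.approx(15 / 16)
        assert max(n.label for n in sched) == 0.938

    def test_full_level_set_matches_the_printed_labels(self):
        sched = build_fractile_schedule(3, edge_refinement=True)
        labels = sorted(n.label for n in sched)
        assert labels == [0.063, 0.125, 0.25, 0.5, 0.75, 0.875, 0.938]

    def test_point_counts_between_seven_and_nine(self):
        # without refinements: 5 CEs + 2 anchors; with: 7 + 2
        assert len(build_fractile_schedule(3, False)) + 2 == 7
        assert len(build_fractile_schedule(3, True)) + 2 == 9


class TestRunFractile:
    def test_perfect_oracle_recovers_points_on_the_truth(self, truth):
        sched = build_fractile_schedule(3)
        pts = run_fractile(lambda g, r: truth.certainty_equivalent(g),
                           sched, repeats=1, rng=0, domain=truth.domain)
        assert len(pts) == 9
        for _, row in pts.iterrows():
            assert truth(row.volume_ml) == pytest.approx(row.utility,
                                                         abs=1e-9)

    def test_anchors_present(self, truth):
        sched = build_fractile_schedule(2)
        pts = run_fractile(lambda g, r: truth.certainty_equivalent(g),
                           sched, repeats=1, rng=0, domain=truth.domain)
        assert {(0.1, 0.0), (1.2, 1.0)} <= set(
            zip(pts.volume_ml.round(9), pts.utility))

    def test_repeats_reduce_point_scatter(self, agent, truth):
        """Averaging 3 staircases per node shrinks CE variance vs 1."""
        from margutil.fractile import agent_ce_oracle

        oracle = agent_ce_oracle(agent)
        root = build_fractile_schedule(1, edge_refinement=False)
        rng = np.random.default_rng(99)
        ces1, ces3 = [], []
        for _ in range(60):
            p1 = run_fractile(oracle, root, 1, rng, domain=truth.domain)
            p3 = run_fractile(oracle, root, 3, rng, domain=truth.domain)
            ces1.append(p1.loc[p1.utility == 0.5, "volume_ml"].item())
            ces3.append(p3.loc[p3.utility == 0.5, "volume_ml"].item())
        assert np.var(ces3) < np.var(ces1)


class TestFitUtility:
    def test_collinear_points_fit_a_line(self, linear_u):
        x = np.linspace(0.1, 1.2, 9)
        pts = np.column_stack([x, (x - 0.1) / 1.1])
        u = fit_utility(pts)
        grid = np.linspace(0.1, 1.2, 200)
        assert np.max(np.abs(u(grid) - (grid - 0.1) / 1.1)) < 1e-6

    def test_noiseless_sshape_recovered_closely(self, truth, truth_fit):
        _, u = truth_fit
        grid = np.linspace(0.1, 1.2, 400)
        assert np.max(np.abs(u(grid) - truth(grid))) <= 0.02

    def test_monotone_output_from_monotone_violating_points(self):
        rng = np.random.default_rng(12)
        grid = np.linspace(0.1, 1.2, 300)
        for seed in range(6):
            x = np.sort(np.r_[0.1, rng.uniform(0.15, 1.15, 7), 1.2])
            y = np.clip(np.linspace(0, 1, 9)
                        + rng.normal(0, 0.08, 9), 0, 1)
            y[0], y[-1] = 0.0, 1.0
            u = fit_utility(np.column_stack([x, y]))
            assert np.all(np.diff(u(grid)) >= -1e-6)
            assert np.all(u.derivative(grid) >= 0)

    def test_endpoints_renormalized(self, truth_fit):
        _, u = truth_fit
        assert u(0.1) == pytest.approx(0.0, abs=1e-12)
        assert u(1.2) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_utility(np.array([[0.1, 0.0], [0.6, 0.5], [1.2, 1.0]]))

    def test_serialization_roundtrip(self, truth_fit):
        _, u = truth_fit
        u2 = UtilityFunction.from_dict(u.to_dict())
        grid = np.linspace(0.1, 1.2, 50)
        assert np.allclose(u(grid), u2(grid))


class TestAverageSessions:
    def test_identical_fits_have_zero_band(self, truth_fit):
        _, u = truth_fit
        grid = np.linspace(0.1, 1.2, 30)
        mean, sd = average_sessions([u, u], grid)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, u(grid))

    def test_constant_offset_pair_gives_delta_over_sqrt2(self):
        lin = UtilityFunction.linear()
        grid = np.linspace(0.25, 1.05, 10)

        class Shifted:
            domain = lin.domain
            def __init__(self, d): self.d = d
            def __call__(self, x): return lin(x) + self.d

        mean, sd = average_sessions([Shifted(0.0), Shifted(0.1)], grid)
        assert np.allclose(sd, 0.1 * 0.7071, atol=1e-4)
        assert np.allclose(mean, lin(grid) + 0.05)

    def test_band_covers_truth_across_sessions(self, utility_sessions,
                                               truth):
        """14 synthetic sessions: mean +/- SD covers the ground truth at
        most grid points."""
        _, fits = utility_sessions
        grid = np.linspace(0.1, 1.2, 100)
        mean, sd = average_sessions(fits, grid)
        inside = (truth(grid) >= mean - sd - 1e-9) \
            & (truth(grid) <= mean + sd + 1e-9)
        assert inside.mean() >= 0.9


class TestMarginalUtility:
    def test_linear_utility_has_constant_slope(self, linear_u):
        for x in (0.2, 0.6, 1.1):
            assert marginal_utility(linear_u, x) == pytest.approx(1 / 1.1,
                                                                  abs=1e-9)

    def test_inverted_u_shape_on_the_sshaped_fit(self, truth_fit):
        _, u = truth_fit
        mid = marginal_utility(u, 0.65)
        assert mid > marginal_utility(u, 0.15)
        assert mid > marginal_utility(u, 1.18)

    def test_derivative_integrates_to_one(self, truth_fit):
        from scipy.integrate import quad
        _, u = truth_fit
        total, _ = quad(lambda x: marginal_utility(u, x), 0.1, 1.2,
                        limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_interval_slope_ordering_matches_fig_3d_logic(self, truth_fit):
        """0.15 ml intervals ending at the three gambles' top outcomes:
        middle interval steepest."""
        _, u = truth_fit
        low = interval_marginal_utility(u, 0.25, 0.40)
        mid = interval_marginal_utility(u, 0.65, 0.80)
        high = interval_marginal_utility(u, 1.05, 1.20)
        assert mid > low and mid > high

    def test_interval_slope_equals_derivative_for_linear(self, linear_u):
        assert interval_marginal_utility(linear_u, 0.3, 0.9) == \
            pytest.approx(marginal_utility(linear_u, 0.5), abs=1e-12)

    def test_shrinking_interval_approaches_the_derivative(self, truth_fit):
        _, u = truth_fit
        x = 0.6
        chord = interval_marginal_utility(u, x - 5e-7, x + 5e-7)
        assert chord == pytest.approx(marginal_utility(u, x), abs=1e-5)

    def test_zero_width_interval_rejected(self, linear_u):
        with pytest.raises(ValueError):
            interval_marginal_utility(linear_u, 0.5, 0.5)


class TestDeming:
    def test_perfect_agreement_gives_unit_slope(self):
        x = np.linspace(0, 1, 12)
        fit = deming_regression(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_axis_swap_gives_reciprocal_slope(self, rng):
        x = rng.uniform(0, 1, 20)
        y = 0.7 * x + 0.1 + rng.normal(0, 0.03, 20)
        f1 = deming_regression(x, y)
        f2 = deming_regression(y, x)
        assert f1.slope == pytest.approx(1 / f2.slope, rel=1e-9)

    def test_out_of_sample_perfect_agent(self, truth_fit):
        """CE measurements that exactly invert the utility give slope 1."""
        _, u = truth_fit
        gambles = sample_validation_gambles(12, rng=5)
        ces = [certainty_equivalent(g, u) for g in gambles]
        full, resid = validate_out_of_sample(u, gambles, ces)
        assert full.slope == pytest.approx(1.0, abs=1e-6)
        assert full.intercept == pytest.approx(0.0, abs=1e-6)
        assert resid.slope == pytest.approx(1.0, abs=1e-4)

    def test_too_few_gambles_rejected(self, truth_fit):
        _, u = truth_fit
        with pytest.raises(ValueError):
            validate_out_of_sample(u, [Gamble.even(0.1, 0.4)], [0.3])


class TestAffineInvariance:
    def test_fit_invariant_under_positive_affine_transform(self, truth):
        """Cardinal utility: rescaling the utility axis of the input
        points leaves the (renormalized) fit unchanged."""
        sched = build_fractile_schedule(3)
        pts = run_fractile(lambda g, r: truth.certainty_equivalent(g),
                           sched, repeats=1, rng=0, domain=truth.domain)
        pts2 = pts.copy()
        pts2["utility"] = 3.0 * pts2["utility"] + 2.0
        u1 = fit_utility(pts, domain=truth.domain)
        u2 = fit_utility(pts2, domain=truth.domain)
        grid = np.linspace(0.1, 1.2, 100)
        assert np.allclose(u1(grid), u2(grid), atol=1e-6)
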