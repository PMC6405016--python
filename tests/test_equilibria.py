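"""Phase-plane machinery: nullclines, rest points, stability, Nash, sweeps."""

import numpy as np
import pytest

from psgame.asymmetric import AsymmetricParams, StrategyPair
from psgame.basic import BasicParams, nash_q
from psgame.equilibria import (
    classify_stability,
    find_equilibria,
    integrate_behavior,
    nash_equilibrium,
    nullclines,
    q1_extinction_threshold,
    sweep_gamma,
    sweep_group_size,
    sweep_theta,
)


class TestNullclines:
    def test_contain_boundary_lines(self):
        p = AsymmetricParams.scenario("B")
        nc = nullclines(p, resolution=0.05)
        for fixed in (0.0, 1.0):
            assert np.any(np.isclose(nc.q1_nullcline[:, 0], fixed))
            assert np.any(np.isclose(nc.q2_nullcline[:, 1], fixed))

    def test_symmetric_parameters_mirror_under_swap(self):
        p = AsymmetricParams(
            alpha11=0.36, alpha12=0.36, alpha21=0.36, alpha22=0.36,
            gamma1=1.2, gamma2=1.2, theta=0.5,
        )
        nc = nullclines(p, resolution=0.1)
        swapped = {(round(b, 9), round(a, 9)) for a, b in nc.q2_nullcline}
        original = {(round(a, 9), round(b, 9)) for a, b in nc.q1_nullcline}
        assert original == swapped

    def test_scenario_c_interior_intersection_exists(self):
        rec = nash_equilibrium(AsymmetricParams.scenario("C"))
        assert 0.0 < rec.q1 < 1.0 and 0.0 < rec.q2 < 1.0


class TestFindEquilibria:
    def test_no_theft_leaves_only_corners(self):
        p = AsymmetricParams(alpha11=0, alpha12=0, alpha21=0, alpha22=0)
        records = find_equilibria(p)
        assert sorted((r.q1, r.q2) for r in records) == [
            (0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0),
        ]

    def test_single_class_edge_matches_basic_nash(self):
        p = AsymmetricParams.scenario("A", theta=1.0)
        expected = nash_q(BasicParams(alpha=0.36, gamma=1.002, G=15.0))
        records = find_equilibria(p)
        assert any(abs(r.q1 - expected) < 1e-8 for r in records)

    def test_residuals_below_tolerance(self, scenario_params):
        for r in find_equilibria(scenario_params):
            assert r.residual < 1e-8


class TestStability:
    def test_embedded_basic_interior_nash_is_attracting(self):
        p = AsymmetricParams.scenario("A", theta=1.0)
        q1 = nash_q(BasicParams(alpha=0.36, gamma=1.002, G=15.0))
        rec = nash_equilibrium(p)
        assert rec.q1 == pytest.approx(q1, abs=1e-8)
        # the 1-D slope of the basic behavioural dynamics at q* is negative
        assert rec.stability in ("stable", "boundary-degenerate")

    def test_origin_unstable_when_both_classes_can_invade(self):
        p = AsymmetricParams.scenario("A")  # G=15 >> gamma/alpha for both
        assert classify_stability(p, StrategyPair(0.0, 0.0)) == "unstable"

    def test_origin_stable_without_theft(self):
        p = AsymmetricParams(alpha11=0, alpha12=0, alpha21=0, alpha22=0)
        assert classify_stability(p, StrategyPair(0.0, 0.0)) == "stable"

    def test_rejects_non_equilibrium_point(self):
        p = AsymmetricParams.scenario("C")
        with pytest.raises(ValueError):
            classify_stability(p, StrategyPair(0.4, 0.4))


class TestNashEquilibrium:
    def test_scenario_b_baseline_all_large_scrounge(self):
        rec = nash_equilibrium(AsymmetricParams.scenario("B"))
        assert rec.q2 == pytest.approx(1.0, abs=1e-9)
        assert rec.q1 < 1.0
        assert rec.is_nash

    def test_scenario_c_interior_point_is_flow_limit(self):
        p = AsymmetricParams.scenario("C")
        rec = nash_equilibrium(p)
        ends = []
        rng = np.random.default_rng(42)
        for _ in range(5):
            start = StrategyPair(*rng.uniform(0.05, 0.95, 2))
            traj = integrate_behavior(p, start)
            ends.append(traj.q[:, -1])
        for e in ends:
            assert abs(e[0] - rec.q1) < 1e-6 and abs(e[1] - rec.q2) < 1e-6

    def test_all_large_group_never_scrounges_in_scenario_c(self):
        for G in (5.0, 15.0, 60.0):
            rec = nash_equilibrium(AsymmetricParams.scenario("C", theta=0.0, G=G))
            assert rec.q2 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [0.0, 1.0])
    def test_single_class_group_agrees_with_basic_closed_form(self, theta):
        p = AsymmetricParams.scenario("A", theta=theta)
        rec = nash_equilibrium(p)
        if theta == 1.0:
            expected = nash_q(BasicParams(alpha=p.alpha11, gamma=p.gamma1, G=p.G))
            assert rec.q1 == pytest.approx(expected, abs=1e-8)
        else:
            expected = nash_q(BasicParams(alpha=p.alpha22, gamma=p.gamma2, G=p.G))
            assert rec.q2 == pytest.approx(expected, abs=1e-8)

    def test_stable_records_are_integration_limits(self):
        p = AsymmetricParams.scenario("C")
        _, stable = nash_equilibrium(p, full=True)
        rng = np.random.default_rng(7)
        for r in stable:
            q1 = min(max(r.q1 + rng.uniform(-0.01, 0.01), 0.001), 0.999)
            q2 = min(max(r.q2 + rng.uniform(-0.01, 0.01), 0.001), 0.999)
            traj = integrate_behavior(p, StrategyPair(q1, q2))
            end = traj.q[:, -1]
            assert abs(end[0] - r.q1) < 1e-6 and abs(end[1] - r.q2) < 1e-6


class TestIntegrateBehavior:
    def test_square_is_forward_invariant(self):
        p = AsymmetricParams.scenario("B")
        traj = integrate_behavior(
            p, StrategyPair(0.01, 0.99), horizon=500.0, settle_tol=None
        )
        assert np.all(traj.q >= 0.0) and np.all(traj.q <= 1.0)

    def test_equilibrium_start_stays_put(self):
        p = AsymmetricParams.scenario("C")
        rec = nash_equilibrium(p)
        traj = integrate_behavior(
            p, StrategyPair(rec.q1, rec.q2), horizon=50.0, settle_tol=None
        )
        assert np.allclose(traj.q[0], rec.q1, atol=1e-8)
        assert np.allclose(traj.q[1], rec.q2, atol=1e-8)

    def test_embedded_basic_game_converges_to_closed_form(self):
        p = AsymmetricParams.scenario("A", theta=1.0)
        traj = integrate_behavior(p, StrategyPair(0.5, 0.5))
        expected = nash_q(BasicParams(alpha=0.36, gamma=1.002, G=15.0))
        assert traj.q[0, -1] == pytest.approx(expected, abs=1e-6)


class TestSweeps:
    def test_group_size_sweep_scenario_b_has_minimum_group_size(self):
        p = AsymmetricParams.scenario("B")
        table = sweep_group_size(p, np.arange(2.0, 41.0, 2.0))
        q1 = table.set_index("G")["q1_star"]
        assert q1.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert q1.iloc[-1] > 0.0
        started = q1 > 1e-9
        # once scrounging appears it persists: a genuine minimum group size
        first = started.idxmax()
        assert (q1.loc[first:] > 1e-9).all()

    def test_scenario_c_large_groups_full_small_scrounging(self):
        p = AsymmetricParams.scenario("C")
        table = sweep_group_size(p, [40.0, 70.0, 100.0])
        assert (table["q1_star"] > 1.0 - 1e-9).all()
        assert (table["q2_star"] < 1.0).all()

    def test_group_average_payoff_nonincreasing_in_G(self, scenario_params):
        table = sweep_group_size(scenario_params, np.arange(2.0, 61.0, 2.0))
        vals = table["group_avg_payoff"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)

    def test_basic_nash_strictly_increasing_in_G_once_positive(self):
        qs = [
            nash_q(BasicParams(alpha=0.4, gamma=1.2, G=g))
            for g in np.arange(1.0, 101.0)
        ]
        positive = [q for q in qs if q > 0]
        assert all(b > a for a, b in zip(positive, positive[1:]))

    def test_gamma_sweep_scenario_b_large_always_scrounge(self):
        p = AsymmetricParams.scenario("B")
        grid = np.array([0.3, 1.2, 2.1, 3.0])
        table = sweep_gamma(p, grid, grid)
        assert (table["q2_star"] > 1.0 - 1e-9).all()

    def test_gamma_sweep_scenario_a_monotone_in_gamma(self):
        p = AsymmetricParams.scenario("A")
        grid = np.array([0.6, 1.2, 1.8, 2.4, 3.0])
        table = sweep_gamma(p, grid, grid)
        for g2, block in table.groupby("gamma2"):
            q1 = block.sort_values("gamma1")["q1_star"].to_numpy()
            assert np.all(np.diff(q1) <= 1e-6)
        for g1, block in table.groupby("gamma1"):
            q1 = block.sort_values("gamma2")["q1_star"].to_numpy()
            assert np.all(np.diff(q1) <= 1e-6)

    def test_extinction_threshold_on_synthetic_table(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "gamma1": [1.0, 2.0] * 3,
                "gamma2": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
                "q1_star": [0.5, 0.0, 0.0, 0.0, 0.0, 0.0],
            }
        )
        assert q1_extinction_threshold(table) == 2.0

    def test_theta_sweep_scenario_b_small_scrounging_rises_with_theta(self):
        p = AsymmetricParams.scenario("B")
        table = sweep_theta(p, [0.2, 0.5, 0.8], [60.0])
        q1 = table.sort_values("theta")["q1_star"].to_numpy()
        assert q1[0] < q1[-1]
        assert np.all(np.diff(q1) >= -1e-9)

    def test_theta_sweep_flags_absent_classes(self):
        p = AsymmetricParams.scenario("C")
        table = sweep_theta(p, [0.0, 1.0], [15.0])
        row0 = table[table["theta"] == 0.0].iloc[0]
        row1 = table[table["theta"] == 1.0].iloc[0]
        assert not row0["small_present"] and row0["q1_star"] == 0.0
        assert not row1["large_present"] and row1["q2_star"] == 0.0
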