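import math

import numpy as np
import pytest

from biofilmosc import (
    ParameterSet,
    State,
    Trajectory,
    doubling_time,
    simulate,
    simulate_growth,
    steady_growth_curve,
    summarize_oscillation,
)
from biofilmosc.dynamics import _local_maxima
from biofilmosc.model import ntss_concentrations


class TestSimulate:
    def test_default_grid_shape(self, table1):
        traj = simulate(table1)
        assert len(traj) == 1001
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(25.0)
        np.testing.assert_allclose(np.diff(traj.times), 0.025)

    def test_trivial_state_stays_at_origin(self, table1):
        traj = simulate(table1, (0.0, 0.0, 0.0), t_end=5.0)
        np.testing.assert_array_equal(traj.states, 0.0)

    def test_states_nonnegative(self, cycle_traj):
        assert cycle_traj.states.min() >= 0.0

    def test_converges_to_limit_cycle(self, table1, attractor_traj):
        """States one period apart agree on the attractor tail."""
        summ = summarize_oscillation(attractor_traj, transient=30.0)
        T = summ.period
        t0 = 50.0
        for name in ("Gp", "A", "Gi"):
            y = attractor_traj[name]
            a = np.interp(t0, attractor_traj.times, y)
            b = np.interp(t0 + T, attractor_traj.times, y)
            assert abs(a - b) / max(abs(a), 1e-6) < 1e-2

    def test_subcritical_supply_decays_to_origin(self, table1):
        traj = simulate(table1.replace(G_E=5.0), (1.0, 1.0, 1.0), t_end=40.0)
        assert np.max(traj.states[-1]) < 1e-4

    def test_intermediate_supply_damps_to_ntss(self, table1):
        p = table1.replace(G_E=20.0)
        traj = simulate(p, (1.0, 1.0, 1.0), t_end=60.0)
        np.testing.assert_allclose(
            traj.states[-1], ntss_concentrations(p), rtol=1e-3
        )

    def test_period_independent_of_initial_conditions(self, table1):
        periods = []
        for init in [(1.0, 1.0, 1.0), (5.0, 2.0, 3.0)]:
            traj = simulate(table1, init, t_end=60.0)
            periods.append(summarize_oscillation(traj, transient=30.0).period)
        assert abs(periods[0] - periods[1]) / periods[0] < 0.005

    def test_tolerance_refinement_does_not_move_answer(self, table1):
        res = []
        for factor in (1.0, 0.5):
            traj = simulate(
                table1, (1.0, 1.0, 1.0), t_end=35.0,
                rtol=1e-8 * factor, atol=1e-10 * factor,
            )
            s = summarize_oscillation(traj, transient=10.0)
            res.append((s.period, s.amplitudes["Gp"], s.amplitudes["A"]))
        for a, b in zip(*res):
            assert abs(a - b) / a < 1e-3

    def test_rejects_bad_arguments(self, table1):
        with pytest.raises(ValueError):
            simulate(table1, (1, 1, 1), t_end=-1.0)
        with pytest.raises(ValueError):
            simulate(table1, (1, -1, 1))


class TestTrajectoryContainer:
    def test_csv_round_trip(self, tmp_path, table1):
        traj = simulate(table1, (1.0, 1.0, 1.0), t_end=2.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time,Gp,A,Gi"
        back = Trajectory.from_csv(path)
        np.testing.assert_allclose(back.states, traj.states, rtol=1e-9)
        assert back.columns == traj.columns

    def test_rejects_inconsistent_shapes(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            Trajectory(np.array([1.0, 0.5]), np.zeros((2, 3)))


class TestOscillationSummary:
    def test_oscillatory_run_summary(self, cycle_traj, ntss):
        s = summarize_oscillation(cycle_traj, transient=10.0)
        assert s.oscillatory and s.n_peaks >= 8
        assert s.period > 0
        for name in ("Gp", "A", "Gi"):
            assert s.amplitudes[name] > 0
        # peak-to-trough exceeds the steady level for Gp (strongly spiked)
        assert s.amplitudes["Gp"] > ntss[0]

    def test_cycle_averages_equal_steady_state(self, attractor_traj, ntss):
        """Time averages over whole periods equal the enclosed unstable
        steady state, as for Lotka-Volterra systems; likewise the A*Gp
        product average equals A_ss*Gp_ss."""
        s = summarize_oscillation(attractor_traj, transient=30.0)
        for i, name in enumerate(("Gp", "A", "Gi")):
            assert abs(s.cycle_averages[name] - ntss[i]) / ntss[i] <= 1e-3
        assert abs(s.bilinear_average - ntss[0] * ntss[1]) / (ntss[0] * ntss[1]) <= 1e-3

    def test_damped_run_is_not_oscillatory(self, table1):
        traj = simulate(table1.replace(G_E=7.0), (1.0, 1.0, 1.0), t_end=40.0)
        s = summarize_oscillation(traj, transient=20.0)
        assert not s.oscillatory
        assert math.isnan(s.period)

    def test_window_too_short_raises(self, cycle_traj):
        with pytest.raises(ValueError):
            summarize_oscillation(cycle_traj, transient=40.0)

    def test_peak_refinement_recovers_sine_period(self):
        t = np.arange(0.0, 20.0, 0.025)
        period = 2.13
        states = np.column_stack(
            [np.ones_like(t), 2 + np.sin(2 * np.pi * t / period), np.ones_like(t)]
        )
        s = summarize_oscillation(Trajectory(t, states), transient=0.5)
        assert s.period == pytest.approx(period, rel=1e-4)


class TestGrowth:
    def test_biomass_strictly_increasing_on_cycle(self, table1):
        traj = simulate_growth(table1, State(1.0, 1.0, 1.0, 1e10), t_end=25.0)
        B = traj["B"]
        assert B[0] == pytest.approx(1e10)
        assert np.all(np.diff(B) > 0)

    def test_growth_requires_biomass(self, table1):
        with pytest.raises(ValueError):
            simulate_growth(table1, State(1.0, 1.0, 1.0), t_end=5.0)

    def test_doubling_time_exact_for_exponential_biomass(self):
        """ln2/r regardless of where the ammonia maxima fall."""
        t = np.arange(0.0, 30.0, 0.025)
        r = 0.31
        states = np.column_stack(
            [np.ones_like(t), 2 + np.sin(2 * np.pi * t / 2.3), np.ones_like(t),
             1e10 * np.exp(r * t)]
        )
        traj = Trajectory(t, states, columns=("Gp", "A", "Gi", "B"))
        assert doubling_time(traj) == pytest.approx(math.log(2) / r, rel=1e-6)

    def test_on_attractor_doubling_time_matches_average_equality(self, table1, ntss):
        """Between consecutive ammonia maxima the average of A*Gp equals
        A_ss*Gp_ss, so on-cycle growth is exponential at rate b*A_ss*Gp_ss."""
        warm = simulate(table1, (1.0, 1.0, 1.0), t_end=40.0)
        y0 = np.append(warm.states[-1], 1e10)
        traj = simulate_growth(table1, y0, t_end=20.0)
        td = doubling_time(traj, transient=2.0)
        closed = math.log(2) / (table1.b * ntss[1] * ntss[0])
        assert closed == pytest.approx(0.693147 / 0.487898, rel=1e-4)
        assert td == pytest.approx(closed, rel=5e-3)

    def test_too_few_maxima_raises(self, table1):
        traj = simulate_growth(table1, State(1.0, 1.0, 1.0, 1e10), t_end=12.0)
        with pytest.raises(ValueError, match="maxima"):
            doubling_time(traj, transient=10.0)

    def test_periodic_retardation_aligns_with_nutrient_minima(self, table1):
        """Growth-rate minima coincide with minima of the A*Gp input."""
        traj = simulate_growth(table1, State(1.0, 1.0, 1.0, 1e10), t_end=30.0)
        w = traj.window(10.0)
        growth_rate = np.gradient(np.log(w["B"]), w.times)
        prod = w["A"] * w["Gp"]
        t_rate_min, _ = _local_maxima(w.times, -growth_rate)
        t_prod_min, _ = _local_maxima(w.times, -prod)
        for t in t_rate_min[1:-1]:
            assert np.min(np.abs(t_prod_min - t)) < 0.15

    def test_steady_growth_curve_closed_form(self, table1, ntss):
        t = np.array([0.0, 1.0, 2.0])
        curve = steady_growth_curve(table1, 1e10, t)
        rate = table1.b * ntss[1] * ntss[0]
        np.testing.assert_allclose(curve, 1e10 * np.exp(rate * t), rtol=1e-12)
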