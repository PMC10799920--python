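"""Integration, observables, summaries and consortium coupling."""

import numpy as np
import pytest

import tmesense as tm
from tmesense.params import ParameterError
from tmesense.simulate import EnvironmentSchedule, Trajectory, simulate_consortium


def logistic_closed_form(t, r, K, N0):
    return K * N0 * np.exp(r * t) / (K + N0 * (np.exp(r * t) - 1.0))


class TestTimeCourse:
    def test_population_matches_logistic_closed_form(self, lldr_direct):
        """Without flipping or lysis the culture is exactly logistic."""
        g = lldr_direct.growth
        traj = tm.simulate_time_course(lldr_direct, tm.EnvironmentSignal(lactate=0),
                                       horizon=48.0, output_step=0.5)
        live = traj.states[:, 0] + traj.states[:, 1]
        expected = logistic_closed_form(traj.time, g.growth_rate,
                                        g.carrying_capacity, g.initial_density)
        assert np.allclose(live, expected, rtol=1e-6)

    def test_uninduced_direct_reports_nothing(self, lldr_direct):
        traj = tm.simulate_time_course(lldr_direct, tm.EnvironmentSignal(lactate=0),
                                       horizon=48.0)
        assert np.allclose(traj.normalized_fluor, 0.0, atol=1e-9)

    def test_states_stay_nonnegative(self, lldr_lysis, saturating_lactate):
        traj = tm.simulate_time_course(lldr_lysis, saturating_lactate, horizon=150.0)
        assert traj.states.min() >= 0.0

    def test_flipped_fraction_monotone_without_lysis(self, lldr_switch,
                                                     saturating_lactate):
        traj = tm.simulate_time_course(lldr_switch, saturating_lactate, horizon=150.0)
        live = traj.states[:, 0] + traj.states[:, 1]
        frac = traj.states[:, 1] / live
        assert np.all(np.diff(frac) >= -1e-9)

    def test_tolerance_stability(self, lldr_switch, saturating_lactate):
        """Halving solver tolerances leaves observables unchanged to 1e-4."""
        kw = dict(horizon=48.0, output_step=1.0)
        t1 = tm.simulate_time_course(lldr_switch, saturating_lactate,
                                     rtol=1e-8, atol=1e-10, **kw)
        t2 = tm.simulate_time_course(lldr_switch, saturating_lactate,
                                     rtol=5e-9, atol=5e-11, **kw)
        scale = np.abs(t1.normalized_fluor).max()
        assert np.allclose(t1.normalized_fluor, t2.normalized_fluor,
                           atol=1e-4 * scale, rtol=1e-4)
        assert np.allclose(t1.od600, t2.od600, rtol=1e-4)

    def test_grid_refinement_keeps_peak_value(self, lldr_switch, saturating_lactate):
        s1 = tm.summarize(tm.simulate_time_course(lldr_switch, saturating_lactate,
                                                  horizon=150.0, output_step=0.5))
        s2 = tm.summarize(tm.simulate_time_course(lldr_switch, saturating_lactate,
                                                  horizon=150.0, output_step=0.25))
        assert s2.peak_value == pytest.approx(s1.peak_value, rel=0.01)

    def test_invalid_horizon_rejected(self, lldr_direct):
        with pytest.raises(ParameterError):
            tm.simulate_time_course(lldr_direct, tm.EnvironmentSignal(), horizon=0.0)

    def test_piecewise_schedule_restarts_cleanly(self, lldr_direct):
        """A schedule repeating the same signal equals a constant run."""
        env = tm.EnvironmentSignal(lactate=5.0)
        sched = EnvironmentSchedule(segments=((0.0, env), (12.0, env), (24.0, env)))
        t_const = tm.simulate_time_course(lldr_direct, env, horizon=48.0)
        t_sched = tm.simulate_time_course(lldr_direct, sched, horizon=48.0)
        assert np.allclose(t_const.normalized_fluor, t_sched.normalized_fluor,
                           rtol=1e-6, atol=1e-9)

    def test_step_up_schedule_induces_late(self, lldr_direct):
        sched = EnvironmentSchedule(segments=(
            (0.0, tm.EnvironmentSignal(lactate=0.0)),
            (24.0, tm.EnvironmentSignal(lactate=10.0)),
        ))
        traj = tm.simulate_time_course(lldr_direct, sched, horizon=48.0)
        assert traj.value_at(24.0) == pytest.approx(0.0, abs=1e-9)
        assert traj.value_at(48.0) > 1.0


class TestDoseResponse:
    def test_empty_grid_rejected(self, lldr_direct):
        with pytest.raises(ParameterError):
            tm.dose_response(lldr_direct, "lactate", [])

    def test_monotone_direct_dose_response(self, lldr_direct):
        curve = tm.dose_response(lldr_direct, "lactate", [0, 0.1, 1, 5, 10])
        assert np.all(np.diff(curve.normalized_fluor) >= -1e-9)

    def test_frame_has_one_row_per_grid_point(self, lldr_direct):
        curve = tm.dose_response(lldr_direct, "lactate", [0, 1, 10])
        assert len(curve.to_frame()) == 3


class TestSummarize:
    def _trajectory(self, signal, strain):
        n = len(signal)
        time = np.arange(n, dtype=float)
        states = np.tile([0.5, 0.0, 0.0, 0.0, 0.0], (n, 1))
        return Trajectory(time=time, states=states,
                          od600=np.full(n, 0.5),
                          total_fluor=np.asarray(signal, dtype=float) + 50.0,
                          normalized_fluor=np.asarray(signal, dtype=float),
                          strain=strain)

    def test_constant_zero_trace(self, lldr_direct):
        s = tm.summarize(self._trajectory(np.zeros(10), lldr_direct))
        assert s.peak_value == 0.0
        assert s.persistence_time == 0.0

    def test_monotone_trace_persists_to_horizon(self, lldr_direct):
        sig = np.linspace(0, 100, 11)
        s = tm.summarize(self._trajectory(sig, lldr_direct), detection_threshold=5.0)
        assert s.persistence_time == 10.0
        assert s.peak_time == 10.0

    def test_peak_not_after_persistence_when_detectable(self, lldr_switch,
                                                        saturating_lactate):
        traj = tm.simulate_time_course(lldr_switch, saturating_lactate, horizon=150.0)
        s = tm.summarize(traj)
        assert s.peak_time <= s.persistence_time <= 150.0


class TestConsortium:
    def test_symmetric_members_keep_equal_shares(self, params):
        strains = [tm.build_strain("pLldR", "SWITCH", params, strain_id=f"m{i}")
                   for i in range(3)]
        cons = simulate_consortium(strains, tm.EnvironmentSignal(lactate=10),
                                   horizon=48.0, output_step=1.0)
        frac = cons.member_fractions()
        assert np.allclose(frac, 1.0 / 3.0, atol=1e-9)

    def test_consortium_of_one_matches_single_simulation(self, lldr_switch,
                                                         saturating_lactate):
        cons = simulate_consortium([lldr_switch], saturating_lactate,
                                   horizon=48.0, output_step=1.0)
        single = tm.simulate_time_course(lldr_switch, saturating_lactate,
                                         horizon=48.0, output_step=1.0)
        got = cons.trajectories[0]
        assert np.allclose(got.normalized_fluor, single.normalized_fluor,
                           rtol=1e-7, atol=1e-9)
        assert np.allclose(got.od600, single.od600, rtol=1e-7)

    def test_lysis_member_share_declines(self, lldr_switch, lldr_lysis,
                                         saturating_lactate):
        """Under saturating induction the lysing member loses its share."""
        import dataclasses
        lysis = dataclasses.replace(lldr_lysis, strain_id="lysis")
        switch = dataclasses.replace(lldr_switch, strain_id="plain")
        cons = simulate_consortium([lysis, switch], saturating_lactate,
                                   horizon=48.0, output_step=1.0)
        share = cons.member_fractions()[0]
        assert share[-1] < share[0]
        assert np.all(np.diff(share) <= 1e-6)
        # cross-check the final share against a fine-tolerance reference
        ref = simulate_consortium([lysis, switch], saturating_lactate,
                                  horizon=48.0, output_step=1.0,
                                  rtol=1e-10, atol=1e-12)
        assert share[-1] == pytest.approx(ref.member_fractions()[0][-1], rel=1e-5)

    def test_mixed_capacity_rejected(self, lldr_switch, params):
        import dataclasses
        other = tm.build_strain("pCadC", "SWITCH",
                                {**params, "carrying_capacity": 2.0},
                                strain_id="other")
        with pytest.raises(ParameterError):
            simulate_consortium([lldr_switch, other], tm.EnvironmentSignal(), 10.0)


class TestQualitativeOrderings:
    def test_switch_amplifies_all_three_promoters(self):
        """At saturating induction the switch outperforms direct expression."""
        envs = {"pLldR": tm.EnvironmentSignal(lactate=10.0),
                "pCadC": tm.EnvironmentSignal(pH=5.3),
                "pPepT": tm.EnvironmentSignal(oxygen=0.0)}
        for promoter, env in envs.items():
            direct = tm.simulate_time_course(tm.default_strain(promoter, "DIRECT"),
                                             env, horizon=48.0)
            switch = tm.simulate_time_course(tm.default_strain(promoter, "SWITCH"),
                                             env, horizon=48.0)
            assert switch.normalized_fluor[-1] > direct.normalized_fluor[-1]

    def test_lysis_population_oscillates_damped(self, params, saturating_lactate):
        """The lysis feedback admits damped population oscillations.

        The expression-dilution-death loop oscillates when growth is fast
        relative to lysis-protein turnover and the death response is sharp;
        the shipped calibration sits in the overdamped regime, so this
        exercises the fast-growth corner of parameter space.
        """
        oscillatory = dict(params, growth_rate=0.8, lysis_protein_decay=0.8,
                           lysis_max_death_rate=0.6, lysis_death_coefficient=4.0)
        strain = tm.build_strain("pLldR", "SWITCH_LYSIS", oscillatory)
        traj = tm.simulate_time_course(strain, saturating_lactate,
                                       horizon=300.0, output_step=0.5)
        live = traj.states[:, 0] + traj.states[:, 1]
        d = np.diff(live)
        sign_changes = int(np.sum(np.abs(np.diff(np.sign(d[np.abs(d) > 1e-10])))) / 2)
        assert sign_changes >= 3
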