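import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iobntsim as ib


class TestControlLaw:
    @pytest.mark.parametrize("pc,expected", [
        (0.3, 0), (0.0, 0), (0.49999, 0),
        (0.5, 1), (0.6, 1), (0.74999, 1),
        (0.75, 2), (0.9, 2), (1.0, 2),
    ])
    def test_piecewise_mapping(self, gains, pc, expected):
        assert ib.control_law(pc, gains) == expected

    def test_out_of_range_rejected(self, gains):
        for pc in (-0.01, 1.01, np.nan):
            with pytest.raises(ValueError):
                ib.control_law(pc, gains)

    @given(pc=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_stage_monotone_in_confidence(self, gains, pc):
        u = ib.control_law(pc, gains)
        assert u in (0, 1, 2)
        if pc < 0.999:
            assert ib.control_law(min(pc + 0.001, 1.0), gains) >= u

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ib.ControlGains(theta1=0.8, theta2=0.5)
        with pytest.raises(ValueError):
            ib.ControlGains(alpha_g=-0.1)


class TestModulation:
    def test_maintenance_returns_baselines(self, gains):
        assert ib.modulate_parameters(0, gains) == (
            gains.omega_base, gains.delta_base, gains.R_base)

    def test_intensive_doubles_dose_at_half_gain(self):
        g = ib.ControlGains(alpha_g=0.5)
        om0, _, _ = ib.modulate_parameters(2, g)
        assert om0 == pytest.approx(2.0 * g.omega_base, rel=1e-12)

    def test_nondecreasing_in_stage(self, gains):
        triples = [ib.modulate_parameters(u, gains) for u in (0, 1, 2)]
        for a, b in zip(triples, triples[1:]):
            assert all(x <= y for x, y in zip(a, b))

    def test_invalid_stage_rejected(self, gains):
        with pytest.raises(ValueError):
            ib.modulate_parameters(3, gains)


class TestSafetyOverride:
    def test_passthrough_when_clear(self, policy):
        state = ib.ControlState()
        assert ib.safety_override(2, 0.0, policy, state, 0.0) == 2

    def test_w_safe_forces_zero(self, policy):
        state = ib.ControlState()
        assert ib.safety_override(2, policy.w_safe, policy, state, 0.0) == 0
        assert any("w_safe" in lbl for _, lbl in state.safety_events)

    def test_guard_fraction_steps_down(self, policy):
        state = ib.ControlState()
        w5 = policy.guard_fraction * policy.w_safe  # at the guard boundary
        eff = ib.safety_override(2, w5, policy, state, 0.0)
        assert eff == 1
        assert any("guard" in lbl for _, lbl in state.safety_events)

    def test_cumulative_limit_latches(self, policy):
        state = ib.ControlState(cumulative_dose=policy.max_cumulative_dose)
        assert ib.safety_override(2, 0.0, policy, state, 0.0) == 0
        assert state.emergency_latched
        # latched forever afterwards
        assert ib.safety_override(2, 0.0, policy, state, 99.0) == 0

    def test_interval_limit(self, policy):
        state = ib.ControlState()
        state.dose_ledger.append((100.0, 0.5, 0.7, 0.01, 60.0))
        assert ib.safety_override(1, 0.0, policy, state, 105.0) == 0
        assert ib.safety_override(1, 0.0, policy, state,
                                  100.0 + policy.min_dose_interval) == 1

    def test_never_raises(self, policy):
        # failsafe contract: garbage input still returns a stage
        state = ib.ControlState()
        assert ib.safety_override(2, float("nan"), policy, state, 0.0) in (0, 1, 2)


class TestClosedLoop:
    def test_zero_confidence_no_doses(self, pk, gains, policy):
        trace = ib.generate_trace("correct", 0.0, horizon=240.0)
        traj, state = ib.run_closed_loop(trace, pk, gains, policy,
                                         horizon=240.0, rtol=1e-6, atol=1e-9)
        assert not state.dose_ledger
        assert np.all(traj["w5"] == 0.0)

    def test_small_w_safe_clips_dosing(self, pk, gains):
        tiny = ib.SafetyPolicy(w_safe=1e-4)
        trace = ib.generate_trace("correct", 1.0, horizon=480.0)
        traj, state = ib.run_closed_loop(trace, pk, gains, tiny,
                                         horizon=480.0, rtol=1e-6, atol=1e-9)
        assert traj["w5"].max() <= tiny.w_safe + 1e-9
        assert any("guard" in lbl or "w_safe" in lbl
                   for _, lbl in state.safety_events)

    def test_higher_confidence_delivers_more(self, pk, gains):
        # generous cap so no safeguard binds
        policy = ib.SafetyPolicy(w_safe=1e3, max_cumulative_dose=1e6,
                                 max_single_dose=1e3)
        doses = []
        for level in (0.6, 0.9):
            trace = ib.generate_trace("correct", level, horizon=240.0)
            _, state = ib.run_closed_loop(trace, pk, gains, policy,
                                          horizon=240.0, rtol=1e-6, atol=1e-9)
            doses.append(state.cumulative_dose)
        assert doses[1] > doses[0]

    def test_false_negative_delays_but_stays_safe(self, pk, gains, policy,
                                                  closed_loop_reference):
        trace = ib.generate_trace("false_negative", 0.9, horizon=1440.0)
        traj, state = ib.run_closed_loop(trace, pk, gains, policy,
                                         rtol=1e-6, atol=1e-9)
        ref_traj, ref_state = closed_loop_reference
        assert traj["w5"].max() <= policy.w_safe + 1e-9
        assert state.cumulative_dose <= ref_state.cumulative_dose
        assert not state.dose_ledger  # clamped below theta1: never doses

    def test_safety_dominance_reference_run(self, policy, closed_loop_reference):
        traj, _ = closed_loop_reference
        assert traj["w5"].max() <= policy.w_safe + 1e-9

    def test_closed_vs_open_loop_overshoot(self, pk, gains, policy):
        trace = ib.generate_trace("false_positive", 0.9, horizon=720.0,
                                  fp_window=(0.0, 720.0))
        closed, _ = ib.run_closed_loop(trace, pk, gains, policy,
                                       horizon=720.0, rtol=1e-6, atol=1e-9)
        open_, _ = ib.run_closed_loop(trace, pk, gains, policy, horizon=720.0,
                                      rtol=1e-6, atol=1e-9, open_loop=True)
        overshoot_closed = max(closed["w5"].max() - policy.w_safe, 0.0)
        overshoot_open = max(open_["w5"].max() - policy.w_safe, 0.0)
        assert overshoot_closed <= overshoot_open
        assert overshoot_open > 0  # open loop genuinely overdoses here

    def test_ledger_consistency(self, closed_loop_reference):
        _, state = closed_loop_reference
        assert state.cumulative_dose == pytest.approx(
            sum(row[1] for row in state.dose_ledger), rel=1e-12)

    def test_u_channel_on_grid(self, closed_loop_reference):
        traj, _ = closed_loop_reference
        assert set(np.unique(traj["u"])) <= {0, 1, 2}
        assert len(traj["u"]) == len(traj)

    def test_default_w_safe_margin(self, pk):
        open_peak = ib.peak_intracellular(ib.simulate_forward(pk, pk.omega_0))[1]
        assert ib.default_w_safe(pk) == pytest.approx(1.2 * open_peak, rel=1e-9)
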