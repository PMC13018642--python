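import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iobntsim as ib
from iobntsim.forward import SA_RANGES, explicit_euler_forward, forward_rhs


def _frozen_params():
    return ib.PKParameters(
        k12=0, k21=0, k10=0, ps=0, Fpv_t=0,
        k1wi=0, k2wi=0, k3wi=0, k5wi=0, kiwi=1e-3,
    )


class TestForwardRHS:
    def test_all_rates_zero_gives_zero_derivative(self):
        p = _frozen_params()
        d = forward_rhs(0.0, [0.1, 0.2, 0.3, 0.4, 0.5, 0.0], p)
        assert np.allclose(d, 0.0)

    def test_isolated_pair_conserves_mass(self):
        p = ib.PKParameters(k10=0, ps=0, Fpv_t=0, k1wi=0, k2wi=0, k3wi=0, k5wi=0)
        d = forward_rhs(0.0, [0.5, 0.0, 0.2, 0.0, 0.0, 0.0], p)
        # d(w1 + w3)/dt = 0 exactly
        assert d[0] + d[2] == pytest.approx(0.0, abs=1e-18)

    def test_empty_compartments_no_uptake(self):
        d = forward_rhs(0.0, [0.1, 0.1, 0.1, 0.0, 0.0, 0.0], ib.PKParameters())
        assert d[4] == 0.0

    def test_nan_state_rejected(self):
        with pytest.raises(ValueError):
            forward_rhs(0.0, [np.nan, 0, 0, 0, 0, 0], ib.PKParameters())

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            forward_rhs(0.0, [-0.1, 0, 0, 0, 0, 0], ib.PKParameters())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ib.PKParameters(k12=-1.0)
        with pytest.raises(ValueError):
            ib.PKParameters(vp_t=0.0)
        with pytest.raises(ValueError):
            ib.PKParameters(k10=np.nan)

    def test_ees_cell_exchange_antisymmetric(self):
        # with vascular couplings off, w4 loses exactly what w5 gains (U_e = 1)
        p = ib.PKParameters(ps=0, Fpv_t=0, k10=0)
        d = forward_rhs(0.0, [0.0, 0.0, 0.0, 0.3, 0.05, 0.0], p)
        assert d[3] == pytest.approx(-d[4], rel=1e-12)


class TestSimulateForward:
    def test_zero_dose_zero_trajectory(self, pk):
        traj = ib.simulate_forward(pk, 0.0, horizon=200.0)
        assert np.all(traj.states == 0.0)

    def test_single_interior_maximum_of_w5(self, default_forward):
        w5 = default_forward["w5"]
        i = int(np.argmax(w5))
        assert 0 < i < len(w5) - 1
        # strictly rising then strictly falling (single interior peak)
        assert np.all(np.diff(w5[: i + 1]) > 0)
        assert np.all(np.diff(w5[i:]) < 0)

    def test_nonnegativity(self, default_forward):
        assert default_forward.states.min() >= 0.0

    def test_mass_decreasing_with_elimination(self, pk, default_forward):
        tracked = (default_forward["w1"] + default_forward["w3"]
                   + default_forward["w_el"])
        # w1+w3+w_el only leaks into the tumor branch via Fpv_t
        assert tracked[0] == pytest.approx(pk.omega_0, rel=1e-9)

    def test_horizon_validation(self, pk):
        with pytest.raises(ValueError):
            ib.simulate_forward(pk, 0.7, horizon=0.0)
        with pytest.raises(ValueError):
            ib.simulate_forward(pk, -0.1)

    def test_grid_shape(self, default_forward):
        assert len(default_forward) == 1441
        assert default_forward.states.shape == (1441, 6)

    def test_ps_increases_peak_w5(self, pk):
        lo, hi = SA_RANGES["ps"]
        peaks = [ib.peak_intracellular(ib.simulate_forward(pk.replace(ps=v), 0.7))[1]
                 for v in np.linspace(lo, hi, 4)]
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_conservation_without_elimination(self):
        p = ib.PKParameters(k10=0, ps=0, Fpv_t=0, k1wi=0, k2wi=0, k3wi=0, k5wi=0)
        traj = ib.simulate_forward(p, 0.7, horizon=2000.0)
        total = traj["w1"] + traj["w3"]
        assert np.allclose(total, 0.7, rtol=1e-6)

    def test_eq15_literal_variant_runs_and_differs(self, pk):
        a = ib.simulate_forward(pk, 0.7, horizon=300.0)
        b = ib.simulate_forward(pk, 0.7, horizon=300.0, eq15_literal=True)
        assert not np.allclose(a["w4"], b["w4"])


class TestClosedFormOracle:
    def test_pure_elimination(self):
        p = ib.PKParameters(k12=0, k21=0, k10=2.1e-3)
        t = np.linspace(0, 500, 50)
        w1, w3 = ib.two_compartment_closed_form(p, 0.7, t)
        assert np.allclose(w1, 0.7 * np.exp(-2.1e-3 * t), rtol=1e-12)
        assert np.allclose(w3, 0.0)

    def test_conservation_without_elimination(self):
        p = ib.PKParameters(k10=0)
        t = np.linspace(0, 3000, 100)
        w1, w3 = ib.two_compartment_closed_form(p, 0.7, t)
        assert np.allclose(w1 + w3, 0.7, rtol=1e-12)

    def test_integrator_matches_closed_form_at_60min(self):
        p = ib.PKParameters(ps=0, Fpv_t=0, k1wi=0, k2wi=0, k3wi=0, k5wi=0)
        traj = ib.simulate_forward(p, 0.7, horizon=60.0)
        w1, w3 = ib.two_compartment_closed_form(p, 0.7, traj.times)
        assert np.allclose(traj["w1"], w1, rtol=1e-6)
        assert np.allclose(traj["w3"], w3, rtol=1e-6, atol=1e-12)

    def test_k21_zero_branch(self):
        p = ib.PKParameters(k21=0.0)
        t = np.linspace(0, 1000, 30)
        w1, w3 = ib.two_compartment_closed_form(p, 1.0, t)
        a = p.k12 + p.k10
        assert np.allclose(w1, np.exp(-a * t), rtol=1e-12)
        assert np.allclose(w3, p.k12 / a * (1 - np.exp(-a * t)), rtol=1e-12)


class TestEulerOracle:
    def test_adaptive_matches_fine_euler_peak(self, pk):
        # coarse but honest: dt=2e-3 Euler over the rise-and-fall window
        euler = explicit_euler_forward(pk, 0.7, horizon=600.0, dt=2e-3)
        adaptive = ib.simulate_forward(pk, 0.7, horizon=600.0)
        _, pk_euler = ib.peak_intracellular(euler)
        _, pk_adaptive = ib.peak_intracellular(adaptive)
        assert pk_adaptive == pytest.approx(pk_euler, rel=1e-3)


class TestPeakIntracellular:
    def test_zero_trajectory(self, pk):
        traj = ib.simulate_forward(pk, 0.0, horizon=10.0)
        t, v = ib.peak_intracellular(traj)
        assert (t, v) == (0.0, 0.0)

    def test_monotone_series_peaks_at_end(self):
        times = np.arange(5.0)
        states = np.zeros((5, 6))
        states[:, 4] = np.arange(5.0)
        traj = ib.Trajectory(times=times, states=states,
                             columns=ib.FORWARD_COLUMNS)
        assert ib.peak_intracellular(traj) == (4.0, 4.0)

    def test_tie_broken_earliest(self):
        times = np.arange(4.0)
        states = np.zeros((4, 6))
        states[:, 4] = [0.0, 1.0, 1.0, 0.5]
        traj = ib.Trajectory(times=times, states=states,
                             columns=ib.FORWARD_COLUMNS)
        assert ib.peak_intracellular(traj)[0] == 1.0


class TestMonotonicityProperties:
    @given(scale=st.floats(1.05, 3.0))
    @settings(max_examples=10, deadline=None)
    def test_peak_w5_increases_with_dose(self, scale):
        p = ib.PKParameters()
        lo = ib.peak_intracellular(ib.simulate_forward(p, 0.5, horizon=600.0,
                                                       rtol=1e-6, atol=1e-9))[1]
        hi = ib.peak_intracellular(ib.simulate_forward(p, 0.5 * scale, horizon=600.0,
                                                       rtol=1e-6, atol=1e-9))[1]
        assert hi > lo

    def test_k10_lowers_plasma_profile(self, pk):
        lo, hi = SA_RANGES["k10"]
        t_fixed = 120
        vals = []
        for v in np.linspace(lo, hi, 4):
            traj = ib.simulate_forward(pk.replace(k10=v), 0.7, horizon=300.0)
            vals.append(traj["w1"][t_fixed])
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_k10_shortens_time_above_threshold(self, pk):
        lo, hi = SA_RANGES["k10"]
        thresh = 0.2
        times_above = []
        for v in (lo, hi):
            traj = ib.simulate_forward(pk.replace(k10=v), 0.7, horizon=1440.0)
            times_above.append(int(np.sum(traj["w1"] > thresh)))
        assert times_above[0] > times_above[1]

    def test_random_draws_stay_nonnegative(self):
        rng = np.random.default_rng(7)
        p0 = ib.PKParameters()
        for _ in range(10):
            kw = {k: rng.uniform(*v) for k, v in SA_RANGES.items()
                  if k != "omega_0" and hasattr(p0, k)}
            p = ib.PKParameters(**kw)
            traj = ib.simulate_forward(p, rng.uniform(0.5, 0.9), horizon=720.0,
                                       rtol=1e-6, atol=1e-9)
            assert traj.states.min() >= 0.0
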