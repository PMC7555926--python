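"""Membrane-model unit tests: rates, currents, resting state, integration."""

import numpy as np
import pytest

from axotrace.axon import (AxonSim, AxonState, gating_rates, integrate,
                           membrane_currents, resting_state,
                           steady_state_gates)
from axotrace.errors import ConfigurationError
from axotrace.parameters import RateSpec


def test_linoid_removable_singularity_takes_analytic_limit():
    spec = RateSpec("linoid", A=1.86, B=-25.4, C=10.3)
    assert spec(-25.4) == pytest.approx(1.86 * 10.3, rel=1e-9)
    # decreasing linoid (A < 0, C < 0) also stays positive through B
    dec = RateSpec("linoid", A=-0.304, B=-25.7, C=-9.16)
    assert dec(-25.7) == pytest.approx(0.304 * 9.16, rel=1e-9)
    assert dec(-80.0) > 0


def test_unit_q10_makes_rates_temperature_independent(default_params):
    p_cold = default_params.with_changes(
        T=25.0, q10={g: 1.0 for g in default_params.q10})
    p_ref = default_params.with_changes(
        T=default_params.T_ref, q10={g: 1.0 for g in default_params.q10})
    v = np.linspace(-100, 40, 29)
    for gate in ("m", "h", "p", "s_n", "n_f", "q"):
        a1, b1 = gating_rates(gate, v, p_cold)
        a2, b2 = gating_rates(gate, v, p_ref)
        np.testing.assert_allclose(a1, a2, rtol=1e-12)
        np.testing.assert_allclose(b1, b2, rtol=1e-12)


def test_q10_scales_rates(default_params):
    p = default_params.with_changes(T=default_params.T_ref + 10.0)
    a_hot, _ = gating_rates("m", -60.0, p)
    a_ref, _ = gating_rates("m", -60.0, default_params)
    assert a_hot / a_ref == pytest.approx(default_params.q10["m"], rel=1e-9)


def test_activation_steady_state_monotone_in_voltage(default_params):
    v = np.linspace(-100, 40, 561)
    a, b = gating_rates("m", v, default_params)
    m_inf = a / (a + b)
    assert np.all(np.diff(m_inf) > 0)
    assert np.all(a >= 0) and np.all(b >= 0)


def test_unknown_gate_id_rejected(default_params):
    with pytest.raises(ConfigurationError):
        gating_rates("x7", -70.0, default_params)


def test_nodal_current_zero_at_leak_reversal_with_closed_gates(default_params):
    p = default_params.with_changes(I_pump=0.0)
    st = AxonState(V_n=p.E_Lk, V_i=p.E_Lk, m=0, h=0, p=0, s_n=0, s_i=0,
                   nf_n=0, nf_i=0, q=0)
    cur = membrane_currents(st, p)
    assert cur["node_total"] == pytest.approx(0.0, abs=1e-12)
    assert cur["coupling"] == pytest.approx(0.0, abs=1e-12)


def test_current_conservation_and_linearity(default_params):
    st = AxonState(V_n=-60.0, V_i=-75.0, m=0.3, h=0.6, p=0.1, s_n=0.2,
                   s_i=0.15, nf_n=0.25, nf_i=0.2, q=0.12)
    cur = membrane_currents(st, default_params)
    node_sum = sum(cur[k] for k in ("Na_t", "Na_p", "Ks_n", "Kf_n", "Lk_n",
                                    "pump_n"))
    inter_sum = sum(cur[k] for k in ("Ks_i", "Kf_i", "H", "Lk_i", "pump_i"))
    assert abs(node_sum - cur["node_total"]) < 1e-9
    assert abs(inter_sum - cur["internode_total"]) < 1e-9
    assert cur["total"] == pytest.approx(node_sum + inter_sum, abs=1e-9)
    # doubling G_NaT doubles the transient Na component only
    cur2 = membrane_currents(
        st, default_params.with_changes(G_NaT=2 * default_params.G_NaT))
    assert cur2["Na_t"] == pytest.approx(2 * cur["Na_t"], rel=1e-12)
    assert cur2["Lk_n"] == cur["Lk_n"]


def test_zero_coupling_when_compartments_equal(default_params):
    gates = steady_state_gates(-80.0, -80.0, default_params)
    st = AxonState(V_n=-80.0, V_i=-80.0, **gates)
    assert membrane_currents(st, default_params)["coupling"] == 0.0


def test_leak_only_axon_rests_at_leak_reversal(default_params):
    p = default_params.with_changes(
        G_NaT=0.0, G_Ks_n=0.0, G_Ks_i=0.0, G_Kf_n=0.0, G_Kf_i=0.0,
        G_H=0.0, I_pump=0.0)
    st = resting_state(p)
    assert st.V_n == pytest.approx(p.E_Lk, abs=1e-6)
    assert st.V_i == pytest.approx(p.E_Lk, abs=1e-6)


def test_pump_reduction_depolarizes_resting_potential(default_params):
    base = resting_state(default_params)
    low = resting_state(default_params.with_changes(
        I_pump=default_params.I_pump - 15.0))
    assert low.V_n > base.V_n


def test_resting_state_is_a_fixed_point_of_integration(default_params):
    sim = AxonSim(default_params)
    rest = sim.resting_state()
    traj, _, _ = sim.run(rest, [], t_end=100.0)
    assert abs(traj.V_n[-1] - rest.V_n) < 1e-3
    # gates equal steady-state values at the resting potentials
    ss = steady_state_gates(rest.V_n, rest.V_i, default_params)
    for g, v in ss.items():
        assert getattr(rest, g) == pytest.approx(v, abs=1e-9)


def test_strong_stimulus_elicits_action_potential(default_params, tracker):
    sim = AxonSim(default_params)
    rest = sim.resting_state()
    amp = 3.0 * tracker.T0
    traj = integrate(rest, default_params, [(0.0, 1.0, amp)], t_end=4.0)
    assert traj.V_n.max() > 0.0
    assert np.argmax(traj.V_n > 0) < np.searchsorted(traj.t, 3.0)
    gates = traj.y[:, 2:]
    assert gates.min() >= 0.0 and gates.max() <= 1.0
    assert np.all(np.isfinite(traj.y))


def test_integration_converges_under_step_halving(default_params):
    sim = AxonSim(default_params)
    rest = sim.resting_state()
    amp = 0.5 * 300.0
    end = []
    for dt in (0.01, 0.005):
        traj = integrate(rest, default_params, [(0.0, 1.0, amp)],
                         t_end=10.0, dt_max=dt)
        end.append(traj.V_n[-1])
    assert abs(end[0] - end[1]) < 1e-2


def test_all_or_none_threshold_behaviour(default_params, tracker):
    sim = AxonSim(default_params)
    rest = sim.resting_state()
    i_star = tracker.T0

    def spikes(amp):
        _, vmax, _ = sim.run(rest, [(0.0, 1.0, amp)], t_end=4.0,
                             record=False, window=(0.0, 4.0))
        return vmax > 0.0

    assert not spikes(0.98 * i_star / 1.0025)   # just below bracket floor
    assert spikes(1.02 * i_star * 1.0025)


def test_temperature_neutral_trajectories_with_unit_q10(default_params):
    q1 = {g: 1.0 for g in default_params.q10}
    pa = default_params.with_changes(T=37.0, q10=q1)
    pb = default_params.with_changes(T=30.0, q10=q1)
    ra, rb = resting_state(pa), resting_state(pb)
    ta = integrate(ra, pa, [(0.0, 1.0, 400.0)], t_end=5.0)
    tb = integrate(rb, pb, [(0.0, 1.0, 400.0)], t_end=5.0)
    np.testing.assert_allclose(ta.y, tb.y, atol=1e-9)


def test_trajectory_export_roundtrip(tmp_path, default_params):
    sim = AxonSim(default_params)
    rest = sim.resting_state()
    traj = integrate(rest, default_params, [(0.0, 0.5, 200.0)], t_end=2.0)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns)[:3] == ["time_ms", "V_n_mV", "V_i_mV"]
    np.testing.assert_allclose(df["V_n_mV"], traj.V_n)
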