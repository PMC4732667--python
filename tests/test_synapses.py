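import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tadnet.synapses import (MgBlockParams, SynapseKinetics, SynapseState,
                             conductance, feedback_ampa, feedback_nmda,
                             inhibitory_gaba, mg_vdep, on_presynaptic_spike,
                             peak_time_and_norm, sensory_ampa, sensory_nmda,
                             steady_state_summation_ratio, synaptic_current)

SHIPPED = [feedback_nmda(0.11), feedback_ampa(0.05), inhibitory_gaba(2.0),
           sensory_nmda(0.15), sensory_ampa(0.6)]


class TestPeakTimeAndNorm:
    @pytest.mark.parametrize("to,tc,t_peak,norm", [
        (5.0, 80.0, 14.787, 0.77927),    # NMDAR
        (1.5, 20.0, 4.2004, 0.74979),    # GABA-A
    ])
    def test_hand_values(self, to, tc, t_peak, norm):
        tp, nm = peak_time_and_norm(to, tc)
        assert tp == pytest.approx(t_peak, abs=2e-3)
        assert nm == pytest.approx(norm, abs=2e-5)

    def test_slow_close_limit(self):
        _, nm = peak_time_and_norm(1.0, 1e6)
        assert nm == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            peak_time_and_norm(5.0, 5.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(to=st.floats(0.05, 50), ratio=st.floats(1.01, 100))
    def test_normalized_waveform_peaks_at_one(self, to, ratio):
        tc = to * ratio
        t_peak, norm = peak_time_and_norm(to, tc)
        assert t_peak > 0 and 0 < norm < 1
        t = np.linspace(0, 10 * tc, 4000)
        wave = (np.exp(-t / tc) - np.exp(-t / to)) / norm
        assert wave.max() == pytest.approx(1.0, abs=1e-3)
        at_peak = (math.exp(-t_peak / tc) - math.exp(-t_peak / to)) / norm
        assert at_peak == pytest.approx(1.0, rel=1e-12)


class TestMgVdep:
    def test_hand_values(self):
        p = MgBlockParams()
        assert mg_vdep(-80.0, p) == pytest.approx(0.03216235361, rel=1e-6)
        assert mg_vdep(0.0, p) == pytest.approx(0.9523809524, rel=1e-6)

    def test_unity_without_magnesium(self):
        p = MgBlockParams(mg_out=0.0)
        v = np.linspace(-120, 60, 50)
        assert np.allclose(mg_vdep(v, p), 1.0)
        assert np.allclose(mg_vdep(v, None), 1.0)

    def test_monotone_increasing_and_bounded(self):
        p = MgBlockParams()
        v = np.linspace(-120, 80, 500)
        w = mg_vdep(v, p)
        assert np.all(np.diff(w) > 0)
        assert np.all((w > 0) & (w <= 1))
        assert mg_vdep(400.0, p) == pytest.approx(1.0, abs=1e-6)


class TestSynapticCurrent:
    def test_zero_at_reversal(self):
        kin = feedback_ampa(1.0)
        assert synaptic_current(1.0, kin.e_rev, kin) == 0.0

    def test_inward_sign_and_scale(self):
        # 1 nS * -70 mV = -0.07 nA
        kin = feedback_ampa(1.0)
        assert synaptic_current(1.0, -70.0, kin) == pytest.approx(-0.07)

    def test_block_scales_current(self):
        # -0.07 nA * 1/(1 + 0.05 e^{5.6}) = -0.004821 nA
        kin = feedback_nmda(1.0)
        i = synaptic_current(1.0, -70.0, kin)
        assert i == pytest.approx(-0.07 * mg_vdep(-70.0, kin.mg_block))
        assert i == pytest.approx(-0.004821, abs=2e-6)


class TestEventDrivenState:
    def test_silent_synapse_stays_zero(self):
        kin = feedback_nmda(2.0)
        state = SynapseState()
        for t in (0.0, 10.0, 500.0):
            assert conductance(state, kin, t) == 0.0

    @pytest.mark.parametrize("kin", SHIPPED,
                             ids=lambda k: k.label)
    def test_single_event_peak_equals_g_peak(self, kin):
        state = SynapseState()
        state.pending.append(5.0)
        t = np.arange(5.0, 5.0 + 12 * kin.tau_close, 0.005)
        g = np.array([state.conductance(kin, ti) for ti in t])
        assert np.all(g >= 0)
        assert g.max() <= kin.g_peak * (1 + 1e-12)
        # at the analytic peak time the conductance is exactly g_peak
        s2 = SynapseState()
        s2.pending.append(5.0)
        assert s2.conductance(kin, 5.0 + kin.t_peak) == pytest.approx(
            kin.g_peak, rel=1e-6)

    def test_zero_exactly_at_delivery(self):
        kin = feedback_nmda(2.0)
        state = SynapseState()
        state.pending.append(3.0)
        assert state.conductance(kin, 3.0) == pytest.approx(0.0)

    def test_transmission_probability(self, rng):
        kin = sensory_nmda(1.0, transmission_p=0.5)
        delivered = 0
        for _ in range(10_000):
            state = SynapseState()
            on_presynaptic_spike(state, kin, 0.0, rng)
            delivered += len(state.pending)
        assert delivered / 10_000 == pytest.approx(0.5, abs=0.015)

    def test_certain_and_impossible_transmission(self, rng):
        state = SynapseState()
        on_presynaptic_spike(state, feedback_nmda(1.0), 2.0, rng)
        assert state.pending == [3.0]  # 1 ms delay
        state = SynapseState()
        kin = SynapseKinetics(5.0, 80.0, 1.0, 0.0, transmission_p=0.0)
        on_presynaptic_spike(state, kin, 2.0, rng)
        assert state.pending == []

    def test_delivery_steps_a_and_b_by_one(self):
        kin = feedback_nmda(1.0)
        state = SynapseState()
        on_presynaptic_spike(state, kin, 0.0, None)
        state.evolve_to(1.0, kin)
        assert state.a == pytest.approx(1.0)
        assert state.b == pytest.approx(1.0)

    def test_matches_fine_step_ode_oracle(self, rng):
        # brute-force Euler integration of the two-exponential system at
        # dt = 1 us, random event train
        kin = feedback_nmda(1.3)
        events = np.sort(rng.uniform(1.0, 60.0, size=12))
        state = SynapseState()
        state.pending = list(events)

        dt = 0.001
        t_grid = np.arange(0.0, 80.0, dt)
        a = b = 0.0
        ev = list(events)
        g_ode = np.zeros_like(t_grid)
        for i, t in enumerate(t_grid):
            while ev and ev[0] <= t:
                ev.pop(0)
                a += 1.0
                b += 1.0
            g_ode[i] = kin.g_peak * (b - a) / kin.norm
            a += -a / kin.tau_open * dt
            b += -b / kin.tau_close * dt

        for t_check in (10.0, 30.0, 70.0):
            s2 = SynapseState()
            s2.pending = list(events)
            g_ev = s2.conductance(kin, t_check)
            i = int(round(t_check / dt))
            assert g_ev == pytest.approx(g_ode[i], rel=1e-3, abs=1e-6)


class TestSummation:
    def test_single_spike_is_unity(self):
        kin = feedback_nmda(1.0)
        assert steady_state_summation_ratio(kin, 20.0, 1) == pytest.approx(
            1.0, rel=1e-9)

    @pytest.mark.parametrize("freq,expected", [(25.0, 2.70), (10.0, 1.43)])
    def test_hand_derived_steady_state(self, freq, expected):
        # geometric-series steady state of the A/B pair at 80 ms closing
        kin = feedback_nmda(1.0)
        ratio = steady_state_summation_ratio(kin, freq, 40)
        assert ratio == pytest.approx(expected, abs=0.01)

    def test_monotone_in_frequency_and_low_freq_limit(self):
        kin = feedback_nmda(1.0)
        freqs = [1.0, 5.0, 10.0, 15.0, 20.0, 25.0, 50.0, 100.0]
        ratios = [steady_state_summation_ratio(kin, f, 40) for f in freqs]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == pytest.approx(1.0, abs=0.02)

    def test_swim_band_stays_under_three(self):
        kin = feedback_nmda(1.0)
        for f in np.arange(10.0, 25.5, 1.0):
            assert steady_state_summation_ratio(kin, f, 40) <= 3.0


def test_kinetics_validation():
    with pytest.raises(ValueError):
        SynapseKinetics(0.0, 80.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        SynapseKinetics(5.0, 5.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        SynapseKinetics(5.0, 80.0, -1.0, 0.0)
    with pytest.raises(ValueError):
        SynapseKinetics(5.0, 80.0, 1.0, 0.0, transmission_p=1.5)


def test_kinetics_roundtrip():
    for kin in SHIPPED:
        assert SynapseKinetics.from_dict(kin.to_dict()) == kin
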