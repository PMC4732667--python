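import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tadnet.channels import (ChannelSpec, GateKinetics, GHKParams,
                             RateFunction, classic_hh_channels, gate_rates,
                             ghk_calcium_current, hh_current)

VOLTAGE_GRID = np.arange(-100.0, 60.1, 0.5)


def classic_gates():
    chans = classic_hh_channels()
    return {g.name: g for spec in chans for g in spec.gates}


class TestGateRates:
    def test_classic_n_steady_state_at_rest(self):
        # alpha/(alpha+beta) for the canonical delayed-rectifier gate at
        # the resting potential
        n = classic_gates()["n"]
        a, b = gate_rates(n, -65.0)
        assert a / (a + b) == pytest.approx(0.3177, abs=2e-4)

    def test_linoid_singularity_is_removable(self):
        # the exp-linear form has a 0/0 point; the series value must agree
        # with direct evaluation arbitrarily close to it
        r = RateFunction("linoid", 0.1, -40.0, 10.0)
        assert r(-40.0) == pytest.approx(0.1 * 10.0, rel=1e-9)
        # the function is smooth through the singular point: the values a
        # hair to either side straddle the limit by the local slope a/2
        assert r(-40.0 + 1e-3) == pytest.approx(r(-40.0), rel=1e-3)
        assert r(-40.0 - 1e-3) == pytest.approx(r(-40.0), rel=1e-3)
        assert r(-40.0 + 1e-7) == pytest.approx(r(-40.0), rel=1e-6)

    @pytest.mark.parametrize("name", ["m", "h", "n"])
    def test_rates_finite_nonneg_and_xinf_bounded(self, name):
        g = classic_gates()[name]
        a, b = gate_rates(g, VOLTAGE_GRID)
        assert np.all(np.isfinite(a)) and np.all(np.isfinite(b))
        assert np.all(a >= 0) and np.all(b >= 0)
        xinf = a / (a + b)
        assert np.all((xinf >= 0) & (xinf <= 1))
        assert np.all(1.0 / (a + b) > 0)

    def test_continuity(self):
        g = classic_gates()["m"]
        v = np.arange(-90.0, 50.0, 1.0)
        a1, _ = gate_rates(g, v)
        a2, _ = gate_rates(g, v + 1e-3)
        assert np.all(np.abs(a2 - a1) <= 0.01 * np.maximum(a1, 1e-9))

    def test_rejects_nonfinite_voltage(self):
        g = classic_gates()["m"]
        with pytest.raises(ValueError):
            gate_rates(g, np.nan)
        with pytest.raises(ValueError):
            gate_rates(g, np.inf)


class TestHHCurrent:
    def k_channel(self, g=36.0, e=-77.0):
        n = classic_gates()["n"]
        return ChannelSpec("k", g, e, gates=(n,))

    def test_zero_at_reversal(self):
        spec = self.k_channel()
        assert hh_current(spec, [0.7], -77.0) == pytest.approx(0.0)
        assert hh_current(spec, [1.0], -77.0) == pytest.approx(0.0)

    def test_hand_value(self):
        # g * n^4 * (V - E) = 36 * 0.5^4 * (-30 + 77)
        spec = self.k_channel()
        assert hh_current(spec, [0.5], -30.0) == pytest.approx(105.75)

    def test_linear_in_density_and_sign_change(self):
        s1, s2 = self.k_channel(10.0), self.k_channel(20.0)
        assert hh_current(s2, [0.5], -30.0) == pytest.approx(
            2 * hh_current(s1, [0.5], -30.0))
        below = hh_current(s1, [0.5], -77.5)
        above = hh_current(s1, [0.5], -76.5)
        assert below < 0 < above

    def test_rejects_gate_out_of_range(self):
        with pytest.raises(ValueError):
            hh_current(self.k_channel(), [1.5], -30.0)

    def test_zero_when_gate_closed(self):
        assert hh_current(self.k_channel(), [0.0], 10.0) == 0.0


class TestGHK:
    def test_no_gradient_no_field_is_zero(self):
        p = GHKParams(1e-6, 5.0, 5.0, 293.0)
        assert ghk_calcium_current(p, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_v0_limit_inward_for_outward_gradient(self):
        p = GHKParams(1e-6, 1e-4, 10.0, 293.0)
        # L'Hopital limit: P * z * F * (ci - co), in uA/cm^2
        assert ghk_calcium_current(p, 0.0) == pytest.approx(-1.9296807,
                                                            rel=1e-6)

    def test_pinned_high_precision_value(self):
        # frozen 40-digit evaluation of the constant-field flux expression
        p = GHKParams(1e-6, 1e-4, 10.0, 293.0)
        assert ghk_calcium_current(p, -60.0) == pytest.approx(
            -9.25157612613, rel=1e-9)

    def test_continuous_at_zero(self):
        p = GHKParams(1e-6, 1e-4, 10.0, 293.0)
        near = ghk_calcium_current(p, 1e-3)
        assert near == pytest.approx(ghk_calcium_current(p, 0.0), rel=1e-4)
        assert (ghk_calcium_current(p, 1e-3)
                == pytest.approx(ghk_calcium_current(p, -1e-3), rel=1e-3))

    def test_inward_at_negative_v(self):
        p = GHKParams(1e-6, 1e-4, 10.0, 293.0)
        v = np.arange(-90.0, 0.0, 5.0)
        assert np.all(ghk_calcium_current(p, v) < 0)

    def test_rejects_bad_concentrations(self):
        with pytest.raises(ValueError):
            GHKParams(1e-6, -1.0, 10.0)
        with pytest.raises(ValueError):
            GHKParams(1e-6, 1e-4, 10.0, temperature=0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(v=st.floats(-100, 60))
def test_every_shipped_gate_is_well_behaved(v):
    from tadnet.neurons import din_config
    from tadnet.channels import ChannelSpec
    specs = [ChannelSpec.from_dict(d) for d in din_config()["channels"]]
    specs += classic_hh_channels()
    for spec in specs:
        for gate in spec.gates:
            a, b = gate.rates(v)
            assert np.isfinite(a) and np.isfinite(b)
            assert a >= 0 and b >= 0
            assert 0.0 <= gate.steady_state(v) <= 1.0
            assert gate.time_constant(v) > 0


def test_channel_spec_roundtrip():
    for spec in classic_hh_channels():
        assert ChannelSpec.from_dict(spec.to_dict()) == spec


def test_channel_spec_requires_one_driving_force():
    with pytest.raises(ValueError):
        ChannelSpec("bad", 1.0, None, None)
    with pytest.raises(ValueError):
        ChannelSpec("bad", 1.0, -70.0, GHKParams(1e-6))
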