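import math

import numpy as np
import pytest
from scipy.integrate import quad

from kernelfield.cable import make_cell, simulate
from kernelfield.membrane import (
    GatedChannel,
    LeakSpec,
    SynapseKernel,
    current_synapse,
    effective_conductance,
    generic_ih,
    linearize_channel,
    shift_leak_reversal,
    synapse_waveform_integral,
)
from kernelfield.morphology import SectionSpec, build_ball_and_sticks

LEAK = LeakSpec(g_L=5e-5, E_L=-70.0)


def _const_channel(g_w, w_inf_val):
    return GatedChannel(
        g_w=g_w, E_w=-45.0,
        omega_inf=lambda V: w_inf_val, tau_w=lambda V: 10.0,
    )


class TestLinearizeChannel:
    def test_conductance_ratio_arithmetic(self):
        ch = _const_channel(LEAK.g_L, 0.5)
        qa = linearize_channel(ch, LEAK, -70.0)
        assert qa.gamma_R == pytest.approx(1.5)

    def test_flat_activation_gives_zero_feedback_and_frozen_equivalence(self):
        ch = _const_channel(2 * LEAK.g_L, 0.3)
        qa = linearize_channel(ch, LEAK, -70.0, mode="quasi_active")
        fr = linearize_channel(ch, LEAK, -70.0, mode="frozen")
        assert qa.eta == pytest.approx(0.0, abs=1e-9)
        assert qa.gamma_R == fr.gamma_R
        # with eta = 0, quasi-active and frozen dynamics coincide
        geom = build_ball_and_sticks([SectionSpec("soma", 30, 30, 1)])
        r = []
        for mode in ("quasi_active", "frozen"):
            cell = make_cell(geom, LEAK, channels=[(0, ch)]).linearized(-70.0, mode)
            n = int(round(100 / 0.0625)) + 1
            inp = np.zeros((n, 1)); inp[: n // 2, 0] = 0.01
            r.append(simulate(cell, 100.0, inputs=inp).V)
        np.testing.assert_allclose(r[0], r[1], atol=1e-12)

    def test_sigmoid_channel_against_closed_form_derivative(self):
        # omega_inf(V) = 1/(1+exp((V+80)/10)); closed-form values at V=-70:
        # s = 1/(1+e), ds/dV = -s(1-s)/10
        s = 1.0 / (1.0 + math.e)
        ch = GatedChannel(
            g_w=2 * LEAK.g_L, E_w=-45.0,
            omega_inf=lambda V: 1.0 / (1.0 + math.exp((V + 80.0) / 10.0)),
            tau_w=lambda V: 25.0,
        )
        qa = linearize_channel(ch, LEAK, -70.0)
        gamma_expected = 1.0 + 2.0 * s
        eta_expected = 2.0 * (-70.0 + 45.0) * (-s * (1 - s) / 10.0)
        assert qa.gamma_R == pytest.approx(gamma_expected, rel=1e-6)
        assert qa.eta == pytest.approx(eta_expected, rel=1e-5)

    def test_out_of_window_voltage_warns(self):
        # zero leak is unconstructible (LeakSpec validates g_L > 0), so the
        # division-by-zero branch is unreachable through the public types
        ch = _const_channel(1e-4, 0.5)
        with pytest.raises(ValueError):
            LeakSpec(g_L=0.0, E_L=-70.0)
        with pytest.warns(UserWarning, match="validity window"):
            linearize_channel(ch, LEAK, -150.0)


class TestLeakReversalShift:
    def test_no_channels_identity(self):
        assert shift_leak_reversal(LEAK, [], -70.0) == -70.0

    def test_zero_driving_force(self):
        ch = GatedChannel(g_w=1e-4, E_w=-70.0,
                          omega_inf=lambda V: 0.4, tau_w=lambda V: 10.0)
        qa = linearize_channel(ch, LEAK, -70.0)
        assert shift_leak_reversal(LEAK, [qa], -70.0) == pytest.approx(-70.0)

    def test_two_channels_settle_at_linearization_voltage(self):
        # steady-state oracle: an input-free linearized cell must rest at V_bar
        geom = build_ball_and_sticks([SectionSpec("soma", 30, 30, 1)])
        ch1 = generic_ih(g_w=2e-4)
        ch2 = GatedChannel(
            g_w=1e-4, E_w=-85.0,
            omega_inf=lambda V: 1.0 / (1.0 + math.exp(-(V + 60.0) / 8.0)),
            tau_w=lambda V: 5.0,
        )
        cell = make_cell(geom, LEAK, channels=[(0, ch1), (0, ch2)])
        lin = cell.linearized(-68.0, mode="quasi_active")
        res = simulate(lin, 2000.0, 0.25, V_init=-61.0)
        assert abs(res.V[0, -1] + 68.0) < 1e-6


class TestCurrentSynapse:
    @pytest.mark.parametrize(
        "G, E_syn, V_bar, expected_nA",
        [
            (0.15, 0.0, -70.0, -0.0105),   # excitatory: inward
            (4.5, -80.0, -70.0, 0.045),    # inhibitory: outward
            (1.0, -70.0, -70.0, 0.0),      # zero driving force
        ],
    )
    def test_amplitudes(self, G, E_syn, V_bar, expected_nA):
        tau1, tau2 = (0.2, 1.8) if E_syn == 0 else (0.1, 9.0)
        I_bar, _ = current_synapse(SynapseKernel(tau1, tau2, E_syn, G), V_bar)
        assert I_bar == pytest.approx(expected_nA, abs=1e-12)


class TestSynapseWaveform:
    @pytest.mark.parametrize("tau1,tau2", [(0.2, 1.8), (0.1, 9.0), (0.5, 2.0)])
    def test_integral_closed_form_matches_quadrature(self, tau1, tau2):
        syn = SynapseKernel(tau1, tau2)
        analytic = synapse_waveform_integral(syn)
        numeric, _ = quad(lambda t: syn.waveform(np.array([t]))[0], 0, 50 * tau2,
                          limit=500)
        assert analytic == pytest.approx(numeric, rel=1e-8)
        assert analytic > 0

    def test_reference_values(self):
        syn = SynapseKernel(0.2, 1.8)
        assert syn.tau_peak == pytest.approx(0.4944, abs=5e-4)
        assert synapse_waveform_integral(syn) == pytest.approx(2.368, abs=1e-3)

    def test_peak_normalization(self):
        for tau1, tau2 in [(0.2, 1.8), (0.1, 9.0), (1.0, 1.001)]:
            syn = SynapseKernel(tau1, tau2)
            assert syn.waveform(np.array([syn.tau_peak]))[0] == pytest.approx(1.0)

    def test_alpha_limit_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            SynapseKernel(1.0, 1.0)


class TestEffectiveConductance:
    def setup_method(self):
        self.areas = np.array([1000.0])  # um^2
        self.syn = SynapseKernel(0.2, 1.8, 0.0, 0.2)

    def test_zero_rates_recover_leak(self):
        g = effective_conductance(LEAK, self.areas, {"ext": np.array([1.0])},
                                  {"ext": 0.0}, {"ext": self.syn})
        np.testing.assert_allclose(g, LEAK.g_L)

    def test_increment_linear_in_rate(self):
        g1 = effective_conductance(LEAK, self.areas, {"ext": np.array([1.0])},
                                   {"ext": 40.0}, {"ext": self.syn})
        g2 = effective_conductance(LEAK, self.areas, {"ext": np.array([1.0])},
                                   {"ext": 80.0}, {"ext": self.syn})
        np.testing.assert_allclose(g2 - LEAK.g_L, 2 * (g1 - LEAK.g_L), rtol=1e-12)

    def test_hand_unit_conversion(self):
        # one synapse at 40/s, 0.2 nS, int f = 2.368933 ms on 1000 um^2:
        # increment = 40 * 0.2e-9 S * 2.368933e-3 / 1e-5 cm^2
        g = effective_conductance(LEAK, self.areas, {"p": np.array([1.0])},
                                  {"p": 40.0}, {"p": self.syn})
        intf = synapse_waveform_integral(self.syn)
        expected = 40 * 0.2e-9 * intf * 1e-3 / (1000 * 1e-8)
        assert g[0] - LEAK.g_L == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative rate"):
            effective_conductance(LEAK, self.areas, {"p": np.array([1.0])},
                                  {"p": -1.0}, {"p": self.syn})


def test_linear_membrane_scales_with_amplitude(toy_cell):
    lin = toy_cell.linearized(-70.0, mode="frozen")
    n = int(round(200 / 0.0625)) + 1
    t = np.arange(n) * 0.0625
    syn = SynapseKernel(0.2, 1.8)
    base = syn.waveform(t - 20.0)[:, None] * 0.01
    r1 = simulate(lin, 200.0, inputs=base)
    r2 = simulate(lin, 200.0, inputs=3.0 * base)
    # relative to the response scale (rounding accumulates over ~3000 steps)
    scale = np.abs(r1.V + 70.0).max()
    np.testing.assert_allclose(
        r2.V - (-70.0), 3.0 * (r1.V - (-70.0)), rtol=1e-9, atol=1e-9 * scale
    )
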