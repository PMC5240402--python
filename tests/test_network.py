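"""Hydraulic-network closed forms against independent linear-algebra/ODE oracles."""

import math

import numpy as np
import pytest

from infusim import network as net
from infusim.config import CatheterSpec, InfusionSetup, PumpChannel
from conftest import (
    ML_H,
    U_DOWNSTEP,
    U_FINAL,
    U_GREEN_OLD,
    U_RED,
    random_two_pump,
)

H = 3600.0


def eigen_time_constants(setup):
    """Relaxation times from the 2-state RC matrix (independent oracle)."""
    g, r = setup.channels
    R1, R2, Rc = g.resistance, r.resistance, setup.catheter.resistance
    den = 1.0 / Rc + 1.0 / R1 + 1.0 / R2
    G = np.array(
        [
            [(1.0 - 1.0 / (R1 * den)) / R1, -1.0 / (R1 * R2 * den)],
            [-1.0 / (R1 * R2 * den), (1.0 - 1.0 / (R2 * den)) / R2],
        ]
    )
    A = -np.diag([1.0 / g.compliance, 1.0 / r.compliance]) @ G
    w = np.linalg.eigvals(A)
    return np.sort(-1.0 / w.real)


class TestTransferFunction:
    def test_denominator_s_coefficient(self, std):
        tfn = net.laplace_transfer_two_pump(std, U_DOWNSTEP)
        # C1 R_cath + C1 R1 + C2 R_cath + C2 R2 = 0.03504 h
        assert tfn["den"][1] == pytest.approx(0.03504 * H, rel=1e-12)
        assert tfn["den"][2] == 1.0

    def test_zero_compliance_kills_transfer(self, std):
        s = std.with_channel("red", compliance=0.0)
        assert net.laplace_transfer_two_pump(s, U_DOWNSTEP)["num"][0] == 0.0

    def test_zero_catheter_resistance_kills_transfer(self, std):
        from dataclasses import replace

        s = replace(std, catheter=replace(std.catheter, resistance=0.0))
        assert net.laplace_transfer_two_pump(s, U_DOWNSTEP)["num"][0] == 0.0

    def test_three_channels_refused(self, std):
        third = PumpChannel("blue", 1e-5, 23.0 * H, ((-3600.0, ML_H),))
        s = InfusionSetup(std.channels + (third,), std.catheter)
        with pytest.raises(net.NetworkError, match="state_space"):
            net.laplace_transfer_two_pump(s, U_DOWNSTEP)


class TestTransientFlow:
    def test_time_constants_match_eigen_oracle(self, std, std_transient):
        th = eigen_time_constants(std)
        assert std_transient.theta_first == pytest.approx(th[0], rel=1e-10)
        assert std_transient.theta_second == pytest.approx(th[1], rel=1e-10)
        # standard values land at ~1.242 s and ~124.90 s
        assert std_transient.theta_first == pytest.approx(1.242, abs=1e-3)
        assert std_transient.theta_second == pytest.approx(124.902, abs=1e-3)

    def test_degenerate_zero_line_resistance(self, std):
        s = std.with_channel("green", resistance=0.0).with_channel("red", resistance=0.0)
        tf = net.transient_flow(s, U_DOWNSTEP)
        C = 1.5e-5
        rc = std.catheter.resistance
        assert tf.theta_first == pytest.approx(0.0, abs=1e-12)
        assert tf.theta_second == pytest.approx(2 * C * rc, rel=1e-12)

    def test_peak_location_closed_form(self, std_transient):
        t = np.linspace(0.0, 50.0, 500_001)
        u = std_transient.u_diff(t)
        t_star = std_transient.peak_time()
        assert t[np.argmax(u)] == pytest.approx(t_star, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_vieta_relations_over_draws(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            s = random_two_pump(rng)
            tf = net.transient_flow(s, U_DOWNSTEP)
            assert tf.theta_first * tf.theta_second == pytest.approx(
                tf.coeff_a * tf.coeff_c, rel=1e-9
            )
            assert tf.theta_first + tf.theta_second == pytest.approx(
                tf.coeff_b, rel=1e-12
            )
            assert 0 < tf.theta_first <= tf.theta_second

    def test_closed_form_matches_ode(self, std_transient, std_ode_flow):
        """Two-exponential transient vs the Kirchhoff state-space oracle."""
        u_cf = std_transient.u_diff(std_ode_flow.times)
        u_ode = std_ode_flow.u_M_diff["red"]
        assert np.max(np.abs(u_cf - u_ode)) / u_cf.max() < 1e-6


class TestDosingErrorVolume:
    def test_standard_value(self, std):
        assert net.dosing_error_volume(std, U_DOWNSTEP) == pytest.approx(0.10305)

    def test_zero_downstep(self, std):
        assert net.dosing_error_volume(std, 0.0) == 0.0

    def test_linearity_in_catheter_resistance(self, std):
        from dataclasses import replace

        s2 = replace(std, catheter=replace(std.catheter, resistance=2 * std.catheter.resistance))
        assert net.dosing_error_volume(s2, U_DOWNSTEP) == pytest.approx(
            2 * net.dosing_error_volume(std, U_DOWNSTEP)
        )

    def test_equals_transient_integral(self, std, std_transient):
        assert std_transient.integral() == pytest.approx(
            net.dosing_error_volume(std, U_DOWNSTEP), rel=1e-9
        )


class TestSyringeExchange:
    def test_zero_duration(self, std):
        assert net.syringe_exchange_error(std, 0.0, red_pump_on=True) == 0.0

    def test_negative_duration_rejected(self, std):
        with pytest.raises(net.NetworkError):
            net.syringe_exchange_error(std, -1.0)

    def test_pump_on_adds_exactly_its_delivery(self, std):
        for T in (10.0, 120.0, 900.0):
            on = net.syringe_exchange_error(std, T, red_pump_on=True)
            off = net.syringe_exchange_error(std, T, red_pump_on=False)
            assert on - off == pytest.approx(U_RED * T, rel=1e-12)

    def test_monotone_and_saturating(self, std):
        T = np.linspace(0.0, 5000.0, 200)
        err = np.array([net.syringe_exchange_error(std, t, red_pump_on=False) for t in T])
        assert np.all(np.diff(err) >= -1e-15)
        # compliance term saturates at C2 R_cath u_old_green = 0.2061 ml
        assert err[-1] == pytest.approx(0.2061, abs=2e-4)

    def test_clamped_network_reaches_same_limit(self, std):
        """Clamping the green line in the ODE network discharges exactly
        C2 R_cath u_old_green of excess red volume (pump running)."""
        s = std.with_channel("green", clamps=((0.0, 1e9),), schedule=((-3600.0, U_GREEN_OLD),))
        t = np.linspace(0.0, 4000.0, 400_001)
        fl = net.state_space_simulate(s, t)
        excess = np.trapezoid(fl.u_M_diff["red"], t)
        assert excess == pytest.approx(0.2061, rel=1e-4)


class TestStateSpace:
    def test_constant_schedules_stay_at_equilibrium(self, std):
        s = std.with_channel("green", schedule=((-3600.0, U_GREEN_OLD),))
        t = np.linspace(0.0, 500.0, 5001)
        fl = net.state_space_simulate(s, t)
        for dev in fl.u_M_diff.values():
            assert np.max(np.abs(dev)) < 1e-15
        assert fl.u_cath == pytest.approx(U_GREEN_OLD + U_RED, rel=1e-12)

    def test_three_channel_symmetry(self, std):
        """Stepping one of three identical channels leaves the other two
        with identical deviations."""
        mk = lambda lbl, sched: PumpChannel(lbl, 1.5e-5, 23.0 * H, sched)
        a = mk("a", ((-3600.0, 6 * ML_H), (0.0, 3 * ML_H)))
        b = mk("b", ((-3600.0, 6 * ML_H),))
        c = mk("c", ((-3600.0, 6 * ML_H),))
        s = InfusionSetup((a, b, c), std.catheter)
        t = np.linspace(0.0, 600.0, 60_001)
        fl = net.state_space_simulate(s, t)
        assert np.allclose(fl.u_M_diff["b"], fl.u_M_diff["c"], atol=1e-12)
        assert np.max(fl.u_M_diff["b"]) > 0  # they do deviate

    def test_volume_conservation(self, std):
        """Integral of the total-flow deviation equals the elastic volume
        released by the compliances between the two steady states."""
        t = np.linspace(0.0, 4000.0, 400_001)
        fl = net.state_space_simulate(std, t)
        released = np.trapezoid(fl.u_cath - (U_FINAL), t)
        g, r = std.channels
        rc = std.catheter.resistance
        # steady pressures: p_i = R_cath * total + R_i * u_i
        dp_g = (rc * (U_GREEN_OLD + U_RED) + g.resistance * U_GREEN_OLD) - (
            rc * U_FINAL + g.resistance * (U_GREEN_OLD - U_DOWNSTEP)
        )
        dp_r = rc * (U_GREEN_OLD + U_RED) - rc * U_FINAL
        expected = g.compliance * dp_g + r.compliance * dp_r
        assert released == pytest.approx(expected, abs=1e-8)

    def test_deviations_vanish_at_long_times(self, std_ode_flow):
        # horizon is 10 theta_second past the last transient: tails < 1e-5 of peak
        for dev in std_ode_flow.u_M_diff.values():
            assert abs(dev[-1]) < 1e-5 * max(1e-30, np.max(np.abs(dev)))

    def test_analytic_trace_matches_ode(self, std_flow_total, std_ode_flow):
        scale = np.max(np.abs(std_ode_flow.u_M_diff["green"]))
        assert np.max(np.abs(std_flow_total.u_cath - std_ode_flow.u_cath)) < 1e-6 * scale
        assert (
            np.max(np.abs(std_flow_total.u_M_diff["green"] - std_ode_flow.u_M_diff["green"]))
            < 1e-6 * scale
        )
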