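import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfbc import solver as sol
from csfbc.boundary_conditions import build_bc, harmonic_shape
from csfbc.constitutive import FluidProperties, MaterialModel
from csfbc.fixtures_io import Waveform

from conftest import make_network


def _sine_flow_bc(group="healthy", mean=0.0, amplitude=1e-8, scheme="B", n=200):
    t = np.arange(n) / n
    shape = Waveform(period=1.0, times=t, values=np.sin(2 * np.pi * t), units="x")
    return build_bc(scheme, group, subject_waveform=shape,
                    pulsatile_amplitude=amplitude, mean_inflow=mean)


class TestNetworkElements:
    def test_poiseuille_resistance_and_inertance(self, fluid):
        net = make_network()
        a, l = net.aqueduct_radius, net.aqueduct_length
        assert net.resistance == pytest.approx(8 * fluid.dynamic_viscosity * l / (math.pi * a**4))
        assert net.inertance == pytest.approx(fluid.density * l / (math.pi * a**2))

    def test_scheme_c_needs_sas_compliance(self, shape):
        bc = build_bc("C", "patient", subject_waveform=shape, pulsatile_amplitude=1e-6)
        with pytest.raises(sol.SolverError, match="compliance"):
            sol.NetworkModel(bc=bc, sas_compliance=0.0)


class TestSimulate:
    def test_steady_state_series_resistance(self):
        """Constant inflow, rigid walls, single resistive outlet: the
        pressure drop settles to (R_aq + R_out) * Q0 (closed form)."""
        Q0 = 5e-9
        bc = _sine_flow_bc(mean=Q0, amplitude=0.0)
        net = sol.NetworkModel(bc=bc, mode="CFD")
        res = sol.simulate(net, n_cycles=8)
        drop = res.pressures["ventricle"][-1] - 500.0
        expected = (net.resistance + net.outlet_resistance) * Q0
        assert drop == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("mode", ["FSI", "CFD"])
    def test_zero_input_stays_at_baseline(self, mode):
        bc = _sine_flow_bc(mean=0.0, amplitude=0.0)
        net = sol.NetworkModel(bc=bc, mode=mode)
        res = sol.simulate(net)
        np.testing.assert_allclose(res.pressures["ventricle"], 500.0, atol=1e-9)
        np.testing.assert_allclose(res.pressures["sas"], 500.0, atol=1e-9)
        np.testing.assert_allclose(res.flows["aqueduct"], 0.0, atol=1e-20)

    def test_rc_frequency_response(self):
        """Sinusoidal inflow into the SAS node (rigid ventricle) against
        the one-pole RC transfer function, at dt = 0.001."""
        R_out, C_S = 1e8, 1e-9  # tau = 0.1 s: transients die well before cycle 5
        amp = 1e-8
        bc = _sine_flow_bc(mean=0.0, amplitude=amp, n=1000)
        net = sol.NetworkModel(bc=bc, mode="CFD", outlet_resistance=R_out, sas_compliance=C_S)
        res = sol.simulate(net, dt=0.001)
        t, p = res.last_cycle(res.pressures["sas"])
        omega = 2 * math.pi
        coeff = np.fft.rfft(p - p.mean()) / p.size
        measured_amp = 2 * abs(coeff[1])
        measured_phase = np.angle(coeff[1])
        H = R_out / (1 + 1j * omega * R_out * C_S)
        expected_amp = amp * abs(H)
        # inflow is sin(wt) = Re{-i e^{iwt}}; response phase adds arg H
        expected_phase = np.angle(-1j * H)
        assert measured_amp == pytest.approx(expected_amp, rel=0.02)
        dphi = (measured_phase - expected_phase + math.pi) % (2 * math.pi) - math.pi
        assert abs(dphi) < 0.02 * 2 * math.pi

    @pytest.mark.parametrize("scheme", ["A", "B", "C"])
    @pytest.mark.parametrize("mode", ["FSI", "CFD"])
    def test_mass_conservation(self, scheme, mode):
        """Discrete ventricle mass balance holds to 1e-10 of peak flow."""
        net = make_network(scheme=scheme, mode=mode)
        res = sol.simulate(net)
        assert res.mass_residual <= 1e-10

    @pytest.mark.parametrize("scheme", ["A", "B", "C"])
    @pytest.mark.parametrize("group", ["healthy", "patient"])
    def test_cycle_periodicity(self, scheme, group):
        """With periodic BCs and defaults, cycles 4 and 5 differ < 1%."""
        net = make_network(scheme=scheme, group=group,
                           amplitude=2e-7 if group == "healthy" else 1e-6)
        res = sol.simulate(net)
        assert res.cycle_periodicity <= 0.01

    @pytest.mark.parametrize("scheme", ["A", "B", "C"])
    def test_first_order_convergence(self, scheme):
        peaks = {}
        net = make_network(scheme=scheme)
        for dt in (0.01, 0.005):
            res = sol.simulate(net, dt=dt)
            _, p = res.last_cycle(res.pressures["sas"])
            peaks[dt] = p.max()
        assert abs(peaks[0.01] - peaks[0.005]) / abs(peaks[0.005]) <= 0.01

    def test_divergence_reported_with_step(self):
        net = make_network()
        net.baseline_pressure = float("nan")
        with pytest.raises(sol.SolverError, match="step"):
            sol.simulate(net)

    def test_result_json_roundtrip(self, tmp_path):
        from csfbc.fixtures_io import read_result_json, write_result_json

        res = sol.simulate(make_network())
        path = tmp_path / "res.json"
        write_result_json(res, path)
        back = read_result_json(path)
        np.testing.assert_allclose(back.flows["aqueduct"], res.flows["aqueduct"], rtol=0, atol=0)
        assert back.cycle_periodicity == res.cycle_periodicity


class TestModePair:
    def test_deterministic(self):
        net = make_network()
        a1, b1 = sol.run_mode_pair(net)
        a2, b2 = sol.run_mode_pair(net)
        np.testing.assert_array_equal(a1.pressures["sas"], a2.pressures["sas"])
        np.testing.assert_array_equal(b1.flows["aqueduct"], b2.flows["aqueduct"])

    def test_cfd_equals_fsi_for_vanishing_compliance(self):
        """A nearly rigid cavity (shear modulus scaled up 1e9x) makes the
        compliant-wall solution collapse onto the rigid-wall one."""
        net = make_network()
        stiff = dataclasses.replace(net, material=MaterialModel(E=584.4e9))
        fsi = sol.simulate(dataclasses.replace(stiff, mode="FSI"))
        cfd = sol.simulate(dataclasses.replace(net, mode="CFD"))
        q_scale = np.max(np.abs(cfd.flows["aqueduct"]))
        assert np.max(np.abs(fsi.flows["aqueduct"] - cfd.flows["aqueduct"])) / q_scale < 1e-3
        for node in ("ventricle", "sas"):
            p_scale = np.max(np.abs(cfd.pressures[node]))
            assert np.max(np.abs(fsi.pressures[node] - cfd.pressures[node])) / p_scale < 1e-3


class TestWomersley:
    def test_no_slip_exact(self, fluid):
        for t in (0.0, 0.13, 0.6):
            assert sol.womersley_velocity(1e-3, t, 1e-3, 2 * math.pi, 50.0, fluid) == 0.0

    def test_radius_out_of_range(self, fluid):
        with pytest.raises(ValueError):
            sol.womersley_velocity(2e-3, 0.0, 1e-3, 2 * math.pi, 50.0, fluid)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(a=st.floats(2e-4, 3e-3), G=st.floats(1.0, 500.0))
    def test_low_alpha_poiseuille_limit(self, a, G):
        """For Womersley number <= 0.1 the profile matches the
        quasi-static Poiseuille profile within 1%."""
        fluid = FluidProperties()
        omega = (0.1 / a) ** 2 * fluid.dynamic_viscosity / fluid.density  # alpha = 0.1
        r = np.linspace(0.0, a, 25)
        u = sol.womersley_velocity(r, 0.0, a, omega, G, fluid)
        u_pois = G * (a**2 - r**2) / (4 * fluid.dynamic_viscosity)
        assert np.max(np.abs(u - u_pois)) <= 0.01 * u_pois.max()

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(alpha=st.floats(0.05, 1.0), a=st.floats(5e-4, 2e-3), G=st.floats(1.0, 200.0))
    def test_flow_matches_rl_element(self, alpha, a, G):
        """Cross-section-integrated Womersley flow equals the R-L
        element's response to the same gradient within 5% for alpha <= 1."""
        fluid = FluidProperties()
        omega = (alpha / a) ** 2 * fluid.dynamic_viscosity / fluid.density
        l = 0.015
        R = 8 * fluid.dynamic_viscosity * l / (math.pi * a**4)
        L = fluid.density * l / (math.pi * a**2)
        Qw = sol.womersley_flow_amplitude(a, omega, G, fluid)
        Qrl = G * l / (R + 1j * omega * L)
        assert abs(Qw - Qrl) / abs(Qw) <= 0.05

    def test_quadrature_consistency(self, fluid):
        """Radial quadrature of the velocity profile reproduces the
        closed-form flow phasor."""
        a, omega, G = 1e-3, 2 * math.pi, 80.0
        r = np.linspace(0, a, 2001)
        t_samples = np.linspace(0, 1, 7, endpoint=False)
        for t in t_samples:
            u = sol.womersley_velocity(r, t, a, omega, G, fluid)
            q_num = np.trapezoid(2 * math.pi * r * u, r)
            q_exact = (sol.womersley_flow_amplitude(a, omega, G, fluid) * np.exp(1j * omega * t)).real
            assert q_num == pytest.approx(q_exact, abs=2e-3 * abs(sol.womersley_flow_amplitude(a, omega, G, fluid)))


class TestPeakVelocity:
    def test_steady_parabolic_factor(self, fluid):
        net = make_network()
        res = sol.simulate(net)
        a = 1.5e-3
        res.flows["aqueduct"] = np.full_like(res.flows["aqueduct"], math.pi * a**2 * 0.5)
        assert sol.peak_aqueduct_velocity(res, a, fluid, "poiseuille") == pytest.approx(1.0)

    def test_zero_flow(self, fluid):
        net = make_network()
        res = sol.simulate(net)
        res.flows["aqueduct"] = np.zeros_like(res.flows["aqueduct"])
        assert sol.peak_aqueduct_velocity(res, 1e-3, fluid, "poiseuille") == 0.0

    def test_womersley_matches_poiseuille_at_low_alpha(self, fluid):
        """At alpha <= 0.1 the harmonic reconstruction reduces to the
        parabolic estimate within 2%."""
        net = make_network(scheme="C", group="healthy", amplitude=2e-7)
        res = sol.simulate(net)
        # rescale the geometry so the fundamental's alpha is 0.1
        a = 0.1 / math.sqrt(2 * math.pi * fluid.density / fluid.dynamic_viscosity)
        up = sol.peak_aqueduct_velocity(res, a, fluid, "poiseuille")
        uw = sol.peak_aqueduct_velocity(res, a, fluid, "womersley")
        assert uw == pytest.approx(up, rel=0.02)

    def test_unknown_method(self, fluid):
        res = sol.simulate(make_network())
        with pytest.raises(ValueError, match="method"):
            sol.peak_aqueduct_velocity(res, 1e-3, fluid, "plug")
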