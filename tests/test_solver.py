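"""Frequency-domain solver, time integration, protocol readout and
point-input measures."""

import numpy as np
import pytest

import fieldpol as fp
from conftest import to_norm


def dc(model, axis, e0=1.0):
    return fp.solve_frequency(model, fp.StimulusSpec(e0, 0.0, axis))


class TestExtracellularProfile:
    def test_origin_and_unit_arithmetic(self, cable):
        model, axis = cable
        v_e = fp.extracellular_profile(model.graph, axis, 1.0)
        s = (model.graph.midpoint - axis.origin) @ axis.direction
        # 1 V/m over 1000 um along the axis drops 1 mV
        i, j = np.argmin(s), np.argmax(s)
        assert abs(v_e[i] - v_e[j]) == pytest.approx((s[j] - s[i]) * 1e-3, rel=1e-12)
        at_origin = np.argmin(np.abs(s))
        assert abs(v_e[at_origin]) <= abs(s[at_origin]) * 1e-3 + 1e-15

    def test_bent_profile_slope_and_continuity(self):
        theta = np.pi / 4
        model, axis = fp.bent_cable_model(fp.BentCableSpec(h=0.6, d=0.4, theta=theta))
        v_e = fp.extracellular_profile(model.graph, axis, 1.0)
        x = model.graph.path_dist_um
        main = x < 0.6 * 500.0
        slope_main = np.polyfit(x[main], v_e[main], 1)[0]
        slope_bent = np.polyfit(x[~main], v_e[~main], 1)[0]
        assert slope_bent / slope_main == pytest.approx(-np.cos(theta), rel=1e-9)
        # continuity at the bend: no jump beyond one compartment's increment
        k = np.argmax(~main)
        assert abs(v_e[k] - v_e[k - 1]) < 2 * abs(slope_main) * (x[k] - x[k - 1]) + 1e-12


class TestAdmittance:
    def test_passive_dc_real(self, cable):
        model, _ = cable
        y = fp.membrane_admittance(model, 0.0)
        assert np.allclose(y.imag, 0.0)
        assert np.allclose(
            y.real, model.g_l * model.graph.area_cm2 * 1e6, rtol=1e-12)

    def test_qa_mu_zero_formula(self, cable):
        model, _ = cable
        qa = fp.QAChannel("qa", model.g_l[0], mu_star=0.0, w_inf_rest=0.5)
        m = fp.build_model(model.graph, g_l=model.g_l, c_m=model.c_m, channels=[qa])
        y = fp.membrane_admittance(m, 10.0)
        area = m.graph.area_cm2
        omega = 2 * np.pi * 10.0 * 1e-3
        expected = (1j * omega * m.c_m * area * 1e3
                    + m.g_l * 1.5 * area * 1e6)
        assert np.allclose(y, expected, rtol=1e-12)

    def test_restorative_raises_dc_conductance(self, cable):
        model, _ = cable
        qa = fp.QAChannel("qa", model.g_l[0], mu_star=2.0)
        frozen_like = fp.QAChannel("qa0", model.g_l[0], mu_star=0.0)
        m1 = fp.build_model(model.graph, g_l=model.g_l, c_m=model.c_m, channels=[qa])
        m0 = fp.build_model(model.graph, g_l=model.g_l, c_m=model.c_m, channels=[frozen_like])
        dy = fp.membrane_admittance(m1, 0.0).real - fp.membrane_admittance(m0, 0.0).real
        expected = 2.0 * model.g_l * model.graph.area_cm2 * 1e6
        assert np.allclose(dy, expected, rtol=1e-12)

    def test_negative_frequency_rejected(self, cable):
        with pytest.raises(ValueError):
            fp.membrane_admittance(cable[0], -1.0)


class TestSolveFrequency:
    def test_zero_field_zero_amplitude(self, cable):
        model, axis = cable
        prof = fp.solve_frequency(model, fp.StimulusSpec(0.0, 10.0, axis))
        assert np.all(prof.amplitude == 0.0)

    def test_straight_cable_closed_form_dc(self, cable):
        model, axis = cable
        prof = dc(model, axis)
        x = model.graph.path_dist_um / 500.0
        ana = np.abs(fp.straight_uniform_sensitivity(1.0, 40.0, 0.0, x))
        assert np.allclose(to_norm(prof.amplitude), ana, rtol=0, atol=5e-3 * ana.max())
        # end phases are 0 (depolarized) and pi (hyperpolarized)
        assert prof.phase[-1] == pytest.approx(0.0, abs=1e-9)
        assert abs(prof.phase[0]) == pytest.approx(np.pi, abs=1e-9)

    def test_linearity_in_field_amplitude(self, cable):
        model, axis = cable
        p1 = fp.solve_frequency(model, fp.StimulusSpec(1.0, 10.0, axis))
        p2 = fp.solve_frequency(model, fp.StimulusSpec(2.0, 10.0, axis))
        assert np.allclose(p1.amplitude, p2.amplitude, rtol=1e-12)

    def test_gauge_invariance(self, cable):
        """Shifting the origin adds a constant to v_e and leaves v unchanged."""
        model, axis = cable
        shifted = fp.FieldAxis(direction=axis.direction,
                               origin=axis.origin + axis.direction * 1234.5)
        a0 = dc(model, axis).amplitude
        a1 = dc(model, shifted).amplitude
        assert np.allclose(a0, a1, atol=1e-12 * a0.max())

    def test_dc_current_conservation(self, cable):
        """The field injects no net membrane current in a sealed system."""
        model, axis = cable
        v_e = fp.extracellular_profile(model.graph, axis, 1.0)
        y = fp.membrane_admittance(model, 0.0).real
        lap = model.graph.axial_laplacian_uS()
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla
        v_i = spla.spsolve((lap + sp.diags(y)).tocsc(), y * v_e)
        total = np.sum(y * (v_i - v_e))
        assert abs(total) < 1e-10 * np.sum(np.abs(y * (v_i - v_e)))

    def test_monotone_frequency_decay_at_ends(self, cable):
        model, axis = cable
        freqs = [0.5, 5.0, 50.0, 500.0]
        ends = [fp.solve_frequency(model, fp.StimulusSpec(1.0, f, axis)).amplitude[-1]
                for f in freqs]
        assert np.all(np.diff(ends) < 0)


class TestTimeDomain:
    def test_zero_field_flat(self, cable):
        model, axis = cable
        tr = fp.solve_time_step(model, fp.StimulusSpec(0.0, 0.0, axis), 50.0,
                                record=[0, model.graph.n - 1])
        assert np.all(tr.v_mV == 0.0)

    def test_dc_step_matches_phasor(self, cable):
        model, axis = cable
        end = model.graph.n - 1
        tr = fp.solve_time_step(model, fp.StimulusSpec(1.0, 0.0, axis), 500.0,
                                record=[end])
        amp = fp.measure_sensitivity_from_trace(tr)[0]
        ref = dc(model, axis).amplitude[end]
        assert amp == pytest.approx(ref, rel=1e-3)

    def test_restorative_overshoot_at_field_onset(self, cable):
        """Uniform restorative QA: DC step transient overshoots steady state."""
        model, axis = cable
        qa = fp.QAChannel("qa", model.g_l[0], mu_star=2.0, tau_w_r=50.0)
        m = fp.build_model(model.graph, g_l=model.g_l, c_m=model.c_m, channels=[qa])
        end = m.graph.n - 1
        tr = fp.solve_time_step(m, fp.StimulusSpec(1.0, 0.0, axis), 800.0, record=[end])
        v = tr.v_mV[0]
        assert v.max() > 1.05 * v[-1]

    def test_nonlinear_channels_rejected_without_linearize(self, cable):
        model, axis = cable
        ch = fp.boltzmann_channel("g", 50e-6, e_rev=-30.0, v_half=-82.0,
                                  slope_mV=-7.0, tau_w_ms=50.0)
        m = fp.build_model(model.graph, g_l=model.g_l, c_m=model.c_m, channels=[ch])
        with pytest.raises(ValueError, match="nonlinear"):
            fp.solve_time_step(m, fp.StimulusSpec(1.0, 0.0, axis), 10.0,
                               linearize=False)


class TestTraceReadout:
    def test_constructed_sinusoid(self):
        t = np.arange(0, 500.0, 0.025)
        trace = fp.TimeTrace(
            t_ms=t,
            v_mV=0.3 * np.sin(2 * np.pi * 10.0 * t * 1e-3)[None, :],
            stimulus=np.sin(2 * np.pi * 10.0 * t * 1e-3),
            locations=np.array([0]), e0=1.0, frequency_hz=10.0)
        amp = fp.measure_sensitivity_from_trace(trace)[0]
        assert amp == pytest.approx(0.3, rel=1e-6)

    def test_ac_protocol_matches_phasor(self, cable):
        model, axis = cable
        end = model.graph.n - 1
        tr = fp.solve_time_step(model, fp.StimulusSpec(1.0, 10.0, axis), 450.0,
                                record=[end])
        amp = fp.measure_sensitivity_from_trace(tr)[0]
        ref = fp.solve_frequency(model, fp.StimulusSpec(1.0, 10.0, axis)).amplitude[end]
        assert amp == pytest.approx(ref, rel=1e-2)

    def test_too_short_trace_rejected(self, cable):
        model, axis = cable
        tr = fp.solve_time_step(model, fp.StimulusSpec(1.0, 10.0, axis), 150.0,
                                record=[0])
        with pytest.raises(ValueError, match="2 cycles"):
            fp.measure_sensitivity_from_trace(tr)


class TestPointInputs:
    def test_single_compartment_ohm(self):
        pts = [fp.SwcPoint(1, 1, 0.0, 0.0, 0.0, 5.0, -1),
               fp.SwcPoint(2, 3, 30.0, 0.0, 0.0, 1.0, 1)]
        graph = fp.build_compartments(pts, 100.0)
        # set leak so that total conductance at the soma is known
        model = fp.build_model(graph, g_l=10e-9 / graph.area_cm2[0], c_m=1.0)
        # soma alone: R = 1 / (g_L area); couple weakly by zeroing dendrite leak
        model.g_l[1:] = 1e-30
        r = fp.input_resistance(model, 0)
        assert r == pytest.approx(100.0, rel=1e-3)

    def test_sealed_cable_coth_closed_form(self):
        model, _ = fp.straight_cable_model(fp.CableSpec(l_um=1000.0))
        r = fp.input_resistance(model, 0)
        g_per_len = model.g_l[0] * 2 * np.pi * 0.25e-4  # S/cm
        r_i = 100.0 / (np.pi * (0.25e-4) ** 2)  # Ohm/cm
        r_inf = np.sqrt(r_i / g_per_len) / 1e6  # MOhm
        x0 = model.graph.path_dist_um[0] / 500.0
        expected = r_inf * np.cosh(2.0 - x0) / np.sinh(2.0)
        assert r == pytest.approx(expected, rel=5e-3)

    def test_transfer_reciprocity_and_field_invariance(self, cable):
        model, axis = cable
        a, b = 3, model.graph.n - 4
        z_ab = fp.transfer_impedance(model, a, b, 10.0)
        z_ba = fp.transfer_impedance(model, b, a, 10.0)
        assert z_ab == pytest.approx(z_ba, rel=1e-10)
        z_field = fp.transfer_impedance(model, a, b, 10.0,
                                        dc_field=fp.StimulusSpec(1.0, 0.0, axis))
        assert z_field == pytest.approx(z_ab, rel=1e-12)

    def test_transfer_impedance_decays_at_high_f(self, cable):
        model, _ = cable
        a, b = 0, model.graph.n - 1
        mags = [abs(fp.transfer_impedance(model, a, b, f))
                for f in (1.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(mags) < 0)
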