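"""Hemodynamics: BP conversion, rheology, waveform, Windkessel, WSS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aaafsi import hemodynamics as h
from aaafsi import io as aio
from aaafsi.wall_fem import GROUP_SHEAR_MODULI_MPA


class TestBloodPressureConversion:
    def test_hand_computed_pair(self):
        bp = h.convert_brachial_to_aa(80, 141)
        assert bp.aa_dia == pytest.approx(70.40)
        assert bp.aa_sys == pytest.approx(148.05)

    def test_cohort_extremes(self):
        """Aortic systolic range over the shipped 30-patient table."""
        recs = aio.read_patient_table()
        sys_vals = [h.convert_brachial_to_aa(r.brachial_dia, r.brachial_sys).aa_sys for r in recs]
        assert round(min(sys_vals), 1) == 108.2
        assert round(max(sys_vals), 1) == 188.0

    def test_unit_factors_give_identity(self):
        bp = h.convert_brachial_to_aa(80, 120, dia_factor=1.0, sys_factor=1.0)
        assert bp.aa_dia == 80 and bp.aa_sys == 120

    def test_unordered_pair_rejected(self):
        with pytest.raises(ValueError):
            h.convert_brachial_to_aa(120, 80)

    @pytest.mark.parametrize(
        "dia,sys,expected", [(90, 120, 100.0), (70.40, 148.05, 96.2833), (80, 80, 80.0)]
    )
    def test_mean_arterial_pressure(self, dia, sys, expected):
        assert h.mean_arterial_pressure(dia, sys) == pytest.approx(expected, abs=1e-3)


class TestCarreau:
    def test_zero_and_infinite_shear_limits(self):
        assert h.carreau_viscosity(0.0) == pytest.approx(0.056)
        assert h.carreau_viscosity(1e12) == pytest.approx(0.00345, rel=1e-3)

    def test_closed_form_at_reciprocal_time_constant(self):
        p = h.CarreauParams()
        expected = 0.00345 + (0.056 - 0.00345) * 2.0 ** ((p.n - 1.0) / 2.0)
        assert h.carreau_viscosity(1.0 / p.lam) == pytest.approx(expected)

    @given(st.floats(min_value=-2, max_value=5))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing(self, log_g):
        g = 10.0**log_g
        assert h.carreau_viscosity(g * 1.01) < h.carreau_viscosity(g)


class TestInletWaveform:
    def test_default_period_and_mean(self):
        wf = h.generic_inlet_waveform()
        assert wf.period == pytest.approx(0.8)
        assert abs(wf.time_average(4000) - 0.96) / 0.96 < 1e-6

    def test_mean_scales_linearly(self):
        wf1 = h.generic_inlet_waveform(mean_flow=0.96)
        wf2 = h.generic_inlet_waveform(mean_flow=1.92)
        t = np.linspace(0, 0.8, 100)
        assert np.allclose(wf2(t), 2.0 * wf1(t))

    def test_triphasic_shape(self):
        t, q = h.generic_inlet_waveform().samples(800)
        assert q.max() > 3.0 * 16.0  # pronounced systolic peak
        assert q.min() < 0.0  # early-diastolic reverse flow

    def test_periodicity(self):
        wf = h.generic_inlet_waveform()
        assert wf(0.1) == pytest.approx(wf(0.1 + 0.8), abs=1e-10)


class TestPoiseuille:
    def test_centerline_velocity(self):
        # q = 16 cm3/s, a = 1 cm -> 2 q / (pi a^2) = 10.19 cm/s
        v = h.inlet_centerline_velocity(16.0, 10.0)
        assert v == pytest.approx(101.9, rel=1e-3)  # mm/s

    def test_zero_flow(self):
        assert h.inlet_centerline_velocity(0.0, 10.0) == 0.0

    def test_wss_formula_and_sign(self):
        g_w = 4 * 16e-6 / (np.pi * 0.01**3)  # 20.37 1/s
        expected = h.carreau_viscosity(g_w) * g_w
        assert h.poiseuille_wss(16.0, 10.0) == pytest.approx(expected)
        assert h.poiseuille_wss(-16.0, 10.0) == pytest.approx(-expected)
        assert h.poiseuille_wss(0.0, 10.0) == 0.0


class TestImpedanceAndWindkessel:
    def test_radius_power_law(self):
        z1 = h.characteristic_impedance(1040, 2e-3, 3e6, 0.5, 0.01)
        z2 = h.characteristic_impedance(1040, 2e-3, 3e6, 0.5, 0.02)
        assert z2 / z1 == pytest.approx(2.0 ** (-2.5))

    def test_direct_formula(self):
        rho, hh, E, nu, a = 1040.0, 2e-3, 2 * 0.92e6 * 1.5, 0.5, 0.01
        expected = np.sqrt(rho * hh * E / (2 * np.pi**2 * (1 - nu**2) * a**5))
        assert h.characteristic_impedance(rho, hh, E, nu, a) == pytest.approx(expected)

    def test_stiffness_square_root_scaling(self):
        z1 = h.characteristic_impedance(1040, 2e-3, 1e6, 0.5, 0.01)
        z4 = h.characteristic_impedance(1040, 2e-3, 4e6, 0.5, 0.01)
        assert z4 / z1 == pytest.approx(2.0)

    def test_initial_estimate(self):
        wk = h.initial_windkessel(96.28, 16.0, Z=6.2271697e7)
        R_T = 96.28 * 133.322 / 16e-6
        assert wk.R == pytest.approx(R_T - 6.2271697e7)
        assert wk.C * wk.R == pytest.approx(0.6)

    def test_zero_impedance_limit(self):
        wk = h.initial_windkessel(100.0, 16.0, Z=1e-6, tau=0.6)
        assert wk.R == pytest.approx(100 * 133.322 / 16e-6, rel=1e-6)

    def test_impedance_exceeding_total_resistance_rejected(self):
        with pytest.raises(ValueError):
            h.initial_windkessel(10.0, 16.0, Z=1e12)

    def test_aaa_compliance(self):
        assert h.estimate_aaa_compliance(1000.0, 1000.0, 70.0, 140.0) == 0.0
        assert h.estimate_aaa_compliance(1000.0, 3000.0, 70.0, 124.0) == pytest.approx(37.037, rel=1e-4)
        with pytest.warns(UserWarning):
            c = h.estimate_aaa_compliance(3000.0, 1000.0, 70.0, 124.0)
        assert c < 0


class ConstantInflow:
    period = 0.8
    mean_flow = 0.96

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, 16.0)
        return float(out) if t.shape == () else out


class TestCircuit:
    def test_constant_inflow_reaches_resistive_steady_state(self):
        wk = h.initial_windkessel(96.28, 16.0, Z=6e7)
        _, p = h.simulate_0d_circuit(ConstantInflow(), wk, n_cycles=12)
        expected = wk.total_resistance * 16e-6 / h.MMHG_TO_PA
        assert p[-1] == pytest.approx(expected, rel=1e-4)

    def test_diastolic_decay_time_constant(self):
        """Zero-inflow decay follows R (C + C_A) (log-linear fit)."""
        wk = h.initial_windkessel(96.28, 16.0, Z=6e7, C_A=h.compliance_si(30.0))

        class Pulse:
            period = 0.8
            mean_flow = 0.96

            def __call__(self, t):
                t = np.asarray(t, dtype=float)
                out = np.where(t % 0.8 < 0.3, 30.0, 0.0)
                return float(out) if t.shape == () else out

        t, p = h.simulate_0d_circuit(Pulse(), wk, n_cycles=12, require_periodic=False)
        seg = (t > 0.45) & (t < 0.78)
        slope = np.polyfit(t[seg], np.log(p[seg]), 1)[0]
        assert -1.0 / slope == pytest.approx(wk.R * (wk.C + wk.C_A), rel=0.02)

    def test_sinusoidal_inflow_matches_transfer_function(self):
        """3-element WK frequency response as analytic oracle (C_A = 0)."""
        wk = h.WindkesselModel(Z=6e7, R=7e8, C=1.2e-9)
        omega = 2 * np.pi / 0.8

        class Sine:
            period = 0.8
            mean_flow = 0.96

            def __call__(self, t):
                t = np.asarray(t, dtype=float)
                out = 16.0 + 5.0 * np.sin(omega * t)
                return float(out) if t.shape == () else out

        t, p = h.simulate_0d_circuit(Sine(), wk, n_cycles=14, require_periodic=False)
        H = wk.Z + wk.R / (1 + 1j * omega * wk.R * wk.C)
        p_exact = (
            wk.total_resistance * 16e-6
            + np.abs(H) * 5e-6 * np.sin(omega * t + np.angle(H))
        ) / h.MMHG_TO_PA
        assert np.max(np.abs(p - p_exact)) / np.ptp(p_exact) < 0.01

    def test_ode_and_frequency_domain_agree(self):
        wf = h.generic_inlet_waveform()
        wk = h.initial_windkessel(96.28, 16.0, Z=6e7, C_A=h.compliance_si(40.0))
        t1, p1 = h.simulate_0d_circuit(wf, wk, n_cycles=12, n_per_cycle=400, require_periodic=False)
        _, p2 = h.periodic_pressure(wf, wk, n_samples=400)
        assert np.max(np.abs(p1 - p2)) < 1e-2


class TestTuning:
    def test_matched_targets_return_immediately(self):
        wf = h.generic_inlet_waveform()
        bp = h.convert_brachial_to_aa(77, 122)
        wk, log = h.tune_windkessel(wf, bp, C_A=h.compliance_si(30.0))
        wk2, log2 = h.tune_windkessel(wf, bp, C_A=h.compliance_si(30.0), init=wk)
        assert len(log2) == 1
        assert wk2.R == wk.R and wk2.C == wk.C

    def test_patient_l8_converges_within_half_mmhg(self):
        wf = h.generic_inlet_waveform()
        bp = h.convert_brachial_to_aa(77, 122)
        ca = h.fusiform_compliance(54.0, 67.0, GROUP_SHEAR_MODULI_MPA["L"])
        wk, log = h.tune_windkessel(wf, bp, C_A=h.compliance_si(ca))
        assert abs(log[-1]["dia"] - bp.aa_dia) <= 0.5
        assert abs(log[-1]["sys"] - bp.aa_sys) <= 0.5

    def test_tuned_model_reproduces_targets_when_resimulated(self):
        wf = h.generic_inlet_waveform()
        bp = h.convert_brachial_to_aa(81, 135)
        ca = h.compliance_si(h.fusiform_compliance(47.0, 75.0, 1.02))
        wk, _ = h.tune_windkessel(wf, bp, C_A=ca)
        _, p = h.periodic_pressure(wf, wk)
        assert abs(p.min() - bp.aa_dia) <= 0.5
        assert abs(p.max() - bp.aa_sys) <= 0.5

    def test_all_30_patients_converge(self):
        """Batch tuning of the full cohort (the per-patient C_A comes from the
        fusiform closed form; criterion is the 0.5 mmHg tuner contract)."""
        wf = h.generic_inlet_waveform()
        for rec in aio.read_patient_table():
            bp = h.convert_brachial_to_aa(rec.brachial_dia, rec.brachial_sys)
            ca = h.fusiform_compliance(
                rec.d_max, rec.l_aaa * 10.0, GROUP_SHEAR_MODULI_MPA[rec.group]
            )
            wk, log = h.tune_windkessel(wf, bp, C_A=h.compliance_si(ca))
            assert abs(log[-1]["dia"] - bp.aa_dia) <= 0.5, rec.id
            assert abs(log[-1]["sys"] - bp.aa_sys) <= 0.5, rec.id
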