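"""Thermogram I/O, baseline estimation, peak integration, rate conversion."""

import json

import numpy as np
import pytest

import itcfit as m
from itcfit.errors import (
    ItcError,
    MonotonicityError,
    ScheduleError,
    ThermogramFormatError,
)


def make_flat(setup, value=0.0, t_end=None):
    t_end = t_end or setup.injections[-1].start_s + 180.0
    t = np.arange(int(t_end) + 1, dtype=float)
    return m.Thermogram(t, np.full_like(t, value), setup)


class TestIO:
    def test_round_trip_lossless(self, tmp_path, default_setup, lactucin_like):
        tg = m.simulate_binding_titration(
            lactucin_like, default_setup,
            noise=m.NoiseModel(power_sigma_ucal_s=0.002, seed=7))
        path = tmp_path / "trace.csv"
        m.write_thermogram(tg, path)
        back = m.read_thermogram(path)
        np.testing.assert_array_equal(back.time_s, tg.time_s)
        np.testing.assert_array_equal(back.power_ucal_s, tg.power_ucal_s)
        assert back.setup == tg.setup
        assert back.provenance == tg.provenance

    def test_missing_sidecar(self, tmp_path, default_setup):
        tg = make_flat(default_setup)
        path = tmp_path / "trace.csv"
        m.write_thermogram(tg, path)
        (tmp_path / "trace.setup.json").unlink()
        with pytest.raises(ThermogramFormatError):
            m.read_thermogram(path)

    def test_bad_header(self, tmp_path):
        path = tmp_path / "trace.csv"
        path.write_text("time_s,power_ucal_per_s\n0,0\n1,0\n")
        path.with_suffix(".setup.json").write_text("{}")
        with pytest.raises(ThermogramFormatError):
            m.read_thermogram(path)

    def test_shuffled_time_column(self, tmp_path, default_setup):
        tg = make_flat(default_setup)
        path = tmp_path / "trace.csv"
        m.write_thermogram(tg, path)
        lines = path.read_text().splitlines()
        lines[2], lines[5] = lines[5], lines[2]  # swap two data rows
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MonotonicityError):
            m.read_thermogram(path)

    def test_overlapping_injections_in_sidecar(self, tmp_path, default_setup):
        tg = make_flat(default_setup)
        path = tmp_path / "trace.csv"
        m.write_thermogram(tg, path)
        sidecar = path.with_suffix(".setup.json")
        d = json.loads(sidecar.read_text())
        d["injections"][1]["start_s"] = d["injections"][0]["start_s"] + 1.0
        sidecar.write_text(json.dumps(d))
        with pytest.raises(ScheduleError):
            m.read_thermogram(path)


class TestBaseline:
    def test_flat_zero_trace(self, default_setup):
        tg = make_flat(default_setup)
        np.testing.assert_array_equal(m.estimate_baseline(tg), 0.0)

    def test_linear_drift_recovered(self, default_setup, lactucin_like):
        drift = 1e-3  # µcal/s per s
        tg = m.simulate_binding_titration(
            lactucin_like, default_setup,
            noise=m.NoiseModel(baseline_drift_ucal_s2=drift, seed=0))
        base = m.estimate_baseline(tg)
        slope = np.polyfit(tg.time_s, base, 1)[0]
        assert slope == pytest.approx(drift, rel=0.02)

    def test_baseline_flat_under_single_pulse(self, default_setup):
        setup = default_setup.with_injections([m.Injection(2.0, 300.0)])
        params = m.BindingParams(n=1.0, kd_um=30.0, dh_kj_mol=-150.0)
        tg = m.simulate_binding_titration(params, setup)
        base = m.estimate_baseline(tg)
        pulse = (tg.time_s > 290) & (tg.time_s < 360)
        assert np.max(np.abs(base[pulse])) < 1e-6


class TestIntegratePeaks:
    def test_zero_trace_zero_heats(self, default_setup):
        hs = m.integrate_peaks(make_flat(default_setup))
        assert np.all(hs.q_ucal == 0.0)

    def test_constructed_pulse_area(self, default_setup):
        """A triangular pulse of known area integrates to 0.1%."""
        setup = default_setup.with_injections([m.Injection(2.0, 300.0)])
        tg0 = make_flat(setup, t_end=600)
        t = tg0.time_s
        width, height = 40.0, -0.5
        tri = np.clip(1 - np.abs(t - 320.0) / (width / 2), 0.0, None) * height
        tg = m.Thermogram(t, tri, setup)
        hs = m.integrate_peaks(tg, baseline=np.zeros_like(t))
        area = height * width / 2
        assert hs.q_ucal[0] == pytest.approx(area, rel=1e-3)

    def test_matches_closed_form_heats(self, default_setup, lactucin_like):
        """sigma=0, tau=0 simulation: q_molar equals closed form / moles."""
        tg = m.simulate_binding_titration(lactucin_like, default_setup,
                                          m.InstrumentModel(0.0))
        hs = m.integrate_peaks(tg)
        q_true = m.expected_injection_heats(lactucin_like, default_setup)
        moles = m.displacement_ledger(default_setup).injected_moles
        np.testing.assert_allclose(hs.q_ucal, q_true, rtol=1e-9)
        expected_molar = q_true / 1e9 * 4.184 / moles
        np.testing.assert_allclose(hs.q_kj_per_mol, expected_molar, rtol=1e-9)

    def test_window_additivity(self, default_setup, lactucin_like):
        """Sum over windows equals the integral of the whole trace."""
        tg = m.simulate_binding_titration(lactucin_like, default_setup,
                                          m.InstrumentModel(0.0))
        hs = m.integrate_peaks(tg, baseline=np.zeros_like(tg.time_s))
        start = default_setup.injections[0].start_s
        mask = tg.time_s >= start
        whole = np.trapezoid(tg.power_ucal_s[mask], tg.time_s[mask])
        assert hs.q_ucal.sum() == pytest.approx(whole, rel=1e-9)

    def test_truncated_window_flagged(self, default_setup, lactucin_like):
        tg = m.simulate_binding_titration(lactucin_like, default_setup,
                                          tail_s=30.0)
        hs = m.integrate_peaks(tg)
        assert hs.truncated[-1]
        assert not hs.truncated[:-1].any()


class TestHeatFlowToRate:
    def test_zero_power_zero_rate(self, kinetics_setup):
        tg = make_flat(kinetics_setup)
        rates = m.heat_flow_to_rate(tg, dh_app_kj_mol=20.0)
        assert np.all(rates["v_um_s"] == 0.0)

    def test_zero_enthalpy_rejected(self, kinetics_setup):
        with pytest.raises(ItcError):
            m.heat_flow_to_rate(make_flat(kinetics_setup), dh_app_kj_mol=0.0)

    def test_round_trip_ideal(self, kinetics_setup, kinetic_truth):
        """tau=0, sigma=0: recovered v matches the simulator's rate."""
        tg = m.simulate_hydrolysis(kinetic_truth, kinetics_setup,
                                   m.InstrumentModel(0.0))
        rates = m.heat_flow_to_rate(tg, kinetic_truth.dh_app_kj_mol)
        v_int = tg._v_internal
        mask = v_int > 0.01
        np.testing.assert_allclose(rates["v_um_s"].to_numpy()[mask],
                                   v_int[mask], rtol=5e-3)

    def test_round_trip_tian_corrected(self, kinetics_setup, kinetic_truth):
        """tau=10 smeared trace, Tian-corrected: v within 2% of the internal
        rate away from injection transients."""
        tg0 = m.simulate_hydrolysis(kinetic_truth, kinetics_setup,
                                    m.InstrumentModel(0.0))
        tg = m.simulate_hydrolysis(kinetic_truth, kinetics_setup,
                                   m.InstrumentModel(10.0))
        rates = m.heat_flow_to_rate(tg, kinetic_truth.dh_app_kj_mol,
                                    tau_s=10.0)
        v_int = tg0._v_internal
        t = tg.time_s
        away = np.ones_like(t, dtype=bool)
        for inj in kinetics_setup.injections:
            away &= ~((t >= inj.start_s - 2) & (t < inj.start_s + 15))
        mask = (v_int > 0.01) & away
        np.testing.assert_allclose(rates["v_um_s"].to_numpy()[mask],
                                   v_int[mask], rtol=0.02)

    def test_substrate_reconstruction(self, kinetics_setup, kinetic_truth):
        tg = m.simulate_hydrolysis(kinetic_truth, kinetics_setup,
                                   m.InstrumentModel(0.0))
        rates = m.heat_flow_to_rate(tg, kinetic_truth.dh_app_kj_mol)
        s_int = tg._s_internal
        mask = s_int > 1.0
        np.testing.assert_allclose(rates["S_um"].to_numpy()[mask],
                                   s_int[mask], rtol=0.02)
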