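"""Single-site isotherm: ledger, predicted heats, fitting, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itcfit as m
from itcfit.binding import bound_concentration
from itcfit.errors import FitError, ScheduleError

from conftest import bisect_bound, brute_force_ledger


class TestDisplacementLedger:
    def test_vanishing_injection_changes_nothing(self, default_setup):
        setup = default_setup.with_injections(
            [m.Injection(1e-9, 60.0, 1e-10)])
        led = m.displacement_ledger(setup)
        assert led.macromolecule_um[0] == pytest.approx(1.0, rel=1e-10)
        assert led.ligand_um[0] == pytest.approx(0.0, abs=1e-8)

    def test_single_injection_dilution_factor(self):
        # 10 µL into 200 µL: f = (1 - 0.025)/(1 + 0.025)
        setup = m.ExperimentSetup(injections=(m.Injection(10.0, 60.0),))
        led = m.displacement_ledger(setup)
        assert led.dilution[0] == pytest.approx((1 - 0.025) / (1 + 0.025),
                                                rel=1e-12)
        assert led.macromolecule_um[0] == pytest.approx(0.951219512, rel=1e-8)

    def test_matches_brute_force_mole_bookkeeping(self, default_setup):
        led = m.displacement_ledger(default_setup)
        macro, lig = brute_force_ledger(default_setup)
        np.testing.assert_allclose(led.macromolecule_um, macro, rtol=1e-9)
        np.testing.assert_allclose(led.ligand_um, lig, rtol=1e-9)

    def test_monotone_concentrations(self, default_setup):
        led = m.displacement_ledger(default_setup)
        assert np.all(np.diff(led.macromolecule_um) < 0)
        assert np.all(np.diff(led.ligand_um) > 0)
        assert np.all(np.diff(led.molar_ratio()) > 0)

    def test_oversized_injection_rejected(self):
        with pytest.raises(ScheduleError):
            m.ExperimentSetup(injections=(m.Injection(250.0, 60.0),))


class TestExpectedHeats:
    def test_zero_enthalpy_gives_zero_heats(self, default_setup):
        params = m.BindingParams(n=1.0, kd_um=10.0, dh_kj_mol=0.0)
        q = m.expected_injection_heats(params, default_setup)
        assert np.all(q == 0.0)

    def test_no_binding_limit(self, default_setup):
        params = m.BindingParams(n=1.0, kd_um=1e12, dh_kj_mol=-100.0)
        q = m.expected_injection_heats(params, default_setup)
        assert np.max(np.abs(q)) < 1e-4  # µcal, vanishing as K_D -> inf

    def test_matches_bisection_oracle(self, default_setup, lactucin_like):
        led = m.displacement_ledger(default_setup)
        b_oracle = np.array([
            bisect_bound(x, mm, lactucin_like.n, lactucin_like.kd_um)
            for x, mm in zip(led.ligand_um, led.macromolecule_um)])
        b = bound_concentration(led.ligand_um, led.macromolecule_um,
                                lactucin_like)
        np.testing.assert_allclose(b, b_oracle, rtol=1e-9)

    def test_monotone_saturation(self, default_setup, lactucin_like):
        """|q_i| non-increasing once the molar ratio passes n (exothermic)."""
        q = m.expected_injection_heats(lactucin_like, default_setup)
        ratios = m.displacement_ledger(default_setup).molar_ratio()
        past = ratios > lactucin_like.n
        assert np.all(np.diff(np.abs(q[past])) <= 1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.floats(0.5, 2.0), kd=st.floats(1.0, 1000.0),
           dh=st.floats(-200.0, 200.0))
    def test_bound_fraction_physical(self, n, kd, dh):
        """0 <= B <= min(X, nM) for any valid parameters."""
        setup = m.ExperimentSetup()
        params = m.BindingParams(n=n, kd_um=kd, dh_kj_mol=dh)
        led = m.displacement_ledger(setup)
        b = bound_concentration(led.ligand_um, led.macromolecule_um, params)
        assert np.all(b >= 0)
        assert np.all(b <= np.minimum(led.ligand_um,
                                      n * led.macromolecule_um) + 1e-12)


class TestFitSingleSite:
    def test_noise_free_self_consistency(self, default_setup, lactucin_like):
        q = m.expected_injection_heats(lactucin_like, default_setup)
        fit = m.fit_single_site(q, default_setup)
        assert fit.converged
        assert fit.params.n == pytest.approx(1.0, rel=1e-6)
        assert fit.params.kd_um == pytest.approx(29.90, rel=1e-6)
        assert fit.params.dh_kj_mol == pytest.approx(-166.93, rel=1e-6)

    def test_noisy_recovery(self, default_setup, lactucin_like):
        """2% first-peak noise, fixed seed: K_D within 10%, dH within 5%."""
        q = m.expected_injection_heats(lactucin_like, default_setup)
        rng = np.random.default_rng(1)
        qn = q + rng.normal(0.0, 0.02 * abs(q[0]), q.size)
        fit = m.fit_single_site(qn, default_setup, fix_n=1.0)
        assert fit.params.kd_um == pytest.approx(29.90, rel=0.10)
        assert fit.params.dh_kj_mol == pytest.approx(-166.93, rel=0.05)

    def test_offset_recovered_params_unbiased(self, default_setup,
                                              lactucin_like):
        q = m.expected_injection_heats(lactucin_like, default_setup) + 0.15
        fit = m.fit_single_site(q, default_setup, fix_n=1.0)
        assert fit.offset_ucal == pytest.approx(0.15, rel=1e-6)
        assert fit.params.kd_um == pytest.approx(29.90, rel=1e-6)

    def test_weak_saturation_flagged(self, default_setup, lactucin_like):
        q = m.expected_injection_heats(lactucin_like, default_setup)
        fit = m.fit_single_site(q, default_setup, fix_n=1.0)
        assert fit.weak_saturation  # c = n[M]/K_D ~ 0.033 < 1

    def test_all_zero_heats_rejected(self, default_setup):
        with pytest.raises(FitError):
            m.fit_single_site(np.zeros(19), default_setup)

    def test_too_few_injections_rejected(self, default_setup):
        with pytest.raises(FitError):
            m.fit_single_site(np.ones(3), default_setup)


class TestDeriveThermodynamics:
    @pytest.mark.parametrize("kd_um, ka_e3", [(29.90, 33.44), (169.00, 5.92)])
    def test_reciprocal_binding_constant(self, kd_um, ka_e3):
        ka, _, _ = m.derive_thermodynamics(kd_um, -100.0, 309.75)
        assert ka / 1e3 == pytest.approx(ka_e3, abs=0.01)

    def test_gibbs_identity_direct(self):
        # dH = -50, T·dS = -30  =>  dG = -20 by dG = dH - T dS
        t = 309.75
        ds = -30.0 * 1000.0 / t
        dh = -50.0
        assert dh - t * ds / 1000.0 == pytest.approx(-20.0, rel=1e-12)

    def test_stored_identities_exact(self):
        ka, dg, ds = m.derive_thermodynamics(29.90, -166.93, 309.75)
        assert abs(ka * 29.90e-6 - 1.0) < 1e-12
        assert dg == pytest.approx(-166.93 - 309.75 * ds / 1000.0, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m.derive_thermodynamics(-1.0, -100.0, 309.75)
        with pytest.raises(ValueError):
            m.derive_thermodynamics(10.0, -100.0, 0.0)

    def test_dg_from_kd_is_rt_log(self):
        ka, dg, _ = m.derive_thermodynamics(29.90, -166.93, 309.75)
        assert dg == pytest.approx(-8.314 * 309.75 * math.log(ka) / 1000.0)
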