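import numpy as np
import pytest

import itcfit as m


@pytest.fixture
def default_setup() -> m.ExperimentSetup:
    """Standard titration: 200 µL cell, 1 µM enzyme, 1 mM syringe,
    19 x 2 µL injections every 180 s."""
    return m.ExperimentSetup()


@pytest.fixture
def lactucin_like() -> m.BindingParams:
    """Realistic exothermic single-site truth (magnitudes from the published
    lactucin row; never a fit target on real data)."""
    return m.BindingParams(n=1.0, kd_um=29.90, dh_kj_mol=-166.93)


@pytest.fixture
def kinetics_setup() -> m.ExperimentSetup:
    """Substrate-accumulation design for Km runs: 12 x 5 µL every 60 s."""
    sched = m.default_schedule(n_injections=12, volume_ul=5.0,
                               spacing_s=60.0, first_start_s=60.0)
    return m.ExperimentSetup(injections=tuple(sched))


@pytest.fixture
def kinetic_truth() -> m.KineticTruth:
    return m.KineticTruth(km_um=48.50, vmax_um_s=0.3)


def bisect_bound(x_um: float, m_um: float, n: float, kd_um: float,
                 iters: int = 200) -> float:
    """Independent equilibrium oracle: bisection on the binding polynomial
    g(B) = (X - B)(nM - B) - K_D B on [0, min(X, nM)]."""
    lo, hi = 0.0, min(x_um, n * m_um)

    def g(b):
        return (x_um - b) * (n * m_um - b) - kd_um * b

    assert g(lo) >= 0 >= g(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def brute_force_ledger(setup: m.ExperimentSetup):
    """Mole-bookkeeping oracle for the displacement ledger: per injection,
    solve the implicit trapezoidal mole balance
    V0 c_after = V0 c_before + c_syr dV - dV (c_before + c_after)/2
    numerically by bisection instead of in closed form."""
    v0 = setup.cell_volume_ul

    def balance(c_before, c_in, dv):
        def f(c_after):
            return (v0 * c_after - v0 * c_before - c_in * dv
                    + dv * 0.5 * (c_before + c_after))

        lo, hi = -1.0, max(c_before, c_in, 1.0) * 2 + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    macro, lig = [], []
    m_cur, x_cur = setup.cell_concentration_um, 0.0
    for inj in setup.injections:
        m_cur = balance(m_cur, 0.0, inj.volume_ul)
        x_cur = balance(x_cur, setup.syringe_concentration_um, inj.volume_ul)
        macro.append(m_cur)
        lig.append(x_cur)
    return np.asarray(macro), np.asarray(lig)
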