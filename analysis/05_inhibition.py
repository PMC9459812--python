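"""Compute the corrected inhibitory activity IA% for each inhibitor
concentration and read off IC50 from the dose curve.

Each "measured" run is composed from its physical contributions on the same
time grid: hydrolysis + substrate-dilution heat, plus inhibitor-dilution
and enzyme-inhibitor heats for inhibited runs.  The IA ledger then removes
exactly those nuisance heats, so the dose curve reflects catalysis alone.
The log-logistic IC50 is cross-checked against the Cheng-Prusoff relation
IC50 = Ki (1 + S/Km) at the mean working substrate concentration.
"""

import argparse

import numpy as np
import pandas as pd

import itcfit as m
from _campaign import (
    DH_APP_KJ_MOL,
    DILUTION_HEAT_UCAL,
    EI_HEAT_UCAL,
    INHIBITOR_UM_GRID,
    INSTRUMENT,
    KI_TRUTH_UM,
    KINETICS_SETUP,
    RESULTS,
    load_or_simulate,
    noise,
    slugify,
)
from itcfit.datasets import KM_ACH_UM
from itcfit.units import ucal_to_kj


def total_molar_heat(tg: m.Thermogram) -> float:
    """Whole-run heat per mole of injectant (kJ/mol), against the
    pre-titration instrument baseline."""
    base = m.instrument_baseline(tg)
    mask = tg.time_s >= tg.setup.injections[0].start_s
    q_ucal = np.trapezoid((tg.power_ucal_s - base)[mask], tg.time_s[mask])
    moles = m.displacement_ledger(tg.setup).injected_moles.sum()
    return ucal_to_kj(float(q_ucal)) / moles


def compose(*tgs: m.Thermogram) -> m.Thermogram:
    power = sum(tg.power_ucal_s for tg in tgs)
    return m.Thermogram(tgs[0].time_s, power, tgs[0].setup)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    traces = load_or_simulate(args.seed)
    dil_s = traces["dilution_substrate"]
    dil_i = m.simulate_dilution_control(
        KINETICS_SETUP, DILUTION_HEAT_UCAL / 2, INSTRUMENT,
        noise(args.seed + 300))
    ei = m.simulate_dilution_control(
        KINETICS_SETUP, EI_HEAT_UCAL, INSTRUMENT, noise(args.seed + 301))

    h_dil_s = total_molar_heat(dil_s)
    h_dil_i = total_molar_heat(dil_i)
    h_ei = total_molar_heat(ei)
    h_hyd = total_molar_heat(compose(traces["hydrolysis_uninhibited"], dil_s))

    rows = []
    for i_um in INHIBITOR_UM_GRID:
        run = compose(traces[slugify(f"hydrolysis I={i_um}uM")],
                      dil_s, dil_i, ei)
        ledger = m.HeatLedger(h_hyd=h_hyd, h_hyd_inh=total_molar_heat(run),
                              h_ei=h_ei, h_dil_s=h_dil_s, h_dil_i=h_dil_i)
        ia = m.inhibitory_activity(ledger).ia_percent
        rows.append({"inhibitor_um": i_um, "ia_percent": ia})
        print(f"I = {i_um:5.2f} µM  ->  IA = {ia:6.2f} %")

    curve = pd.DataFrame(rows)
    res = m.ic50(curve.to_numpy())
    print(f"\nIC50 (log-logistic dose curve) = {res.ic50_um:.2f} µmol/L")

    # Cheng-Prusoff cross-check at the mean working substrate concentration
    pts = m.extract_rate_points(traces["hydrolysis_uninhibited"],
                                DH_APP_KJ_MOL, tau_s=INSTRUMENT.response_tau_s)
    s_bar = float(pts["S_um"].mean())
    cp = m.ic50_cheng_prusoff(KI_TRUTH_UM, s_bar, KM_ACH_UM)
    print(f"Cheng-Prusoff at S = {s_bar:.0f} µM: "
          f"IC50 = {cp:.2f} µmol/L (Ki truth {KI_TRUTH_UM})")

    out = RESULTS / "inhibition.csv"
    curve.assign(ic50_um=res.ic50_um, cheng_prusoff_um=cp).to_csv(
        out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
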