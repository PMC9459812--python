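"""Estimate Km/Vmax from the uninhibited hydrolysis run and Ki from each
inhibited run (competitive model, Km and Vmax held fixed).

Rates are pseudo-steady-state medians shortly after each substrate
injection, after Tian correction of the instrument response.
"""

import argparse

import pandas as pd

import itcfit as m
from _campaign import (
    DH_APP_KJ_MOL,
    INHIBITOR_UM_GRID,
    INSTRUMENT,
    KI_TRUTH_UM,
    RESULTS,
    load_or_simulate,
    slugify,
)
from itcfit.datasets import KM_ACH_UM


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    traces = load_or_simulate(args.seed)
    tau = INSTRUMENT.response_tau_s

    pts = m.extract_rate_points(traces["hydrolysis_uninhibited"],
                                DH_APP_KJ_MOL, tau_s=tau)
    base = m.fit_km(pts)
    print(f"Km  = {base.km_um:7.2f} ± {base.se_km_um:.2f} µmol/L "
          f"(truth {KM_ACH_UM}, err {abs(base.km_um/KM_ACH_UM-1):.1%})")
    print(f"Vmax = {base.vmax_um_s:.4f} ± {base.se_vmax_um_s:.4f} µmol/L/s")

    rows = [{"run": "uninhibited", "inhibitor_um": 0.0,
             "km_um": base.km_um, "vmax_um_s": base.vmax_um_s,
             "ki_um": None, "ki_se_um": None}]
    for i_um in INHIBITOR_UM_GRID:
        tg = traces[slugify(f"hydrolysis I={i_um}uM")]
        pts_i = m.extract_rate_points(tg, DH_APP_KJ_MOL, tau_s=tau,
                                      inhibitor_um=i_um)
        fit = m.fit_ki(pts_i, base)
        rows.append({"run": f"I={i_um}uM", "inhibitor_um": i_um,
                     "km_um": base.km_um, "vmax_um_s": base.vmax_um_s,
                     "ki_um": fit.ki_um, "ki_se_um": fit.se_ki_um})
        print(f"I = {i_um:5.2f} µM: Ki = {fit.ki_um:.3f} ± "
              f"{fit.se_ki_um:.3f} µmol/L (truth {KI_TRUTH_UM})")

    out = RESULTS / "kinetics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
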