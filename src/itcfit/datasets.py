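"""Published reference measurements for chicory-root SL extracts.

Two tables transcribed from the published study of AChE inhibition by
chicory sesquiterpene lactones: the extract composition profiles
(g/100 g dry basis) and the ITC thermodynamic parameters per inhibitor.
The thermodynamic values serve as realistic magnitudes for simulations and
as inputs to the bookkeeping checks (K_A = 1/K_D, composition totals); the
raw thermograms behind them are not publicly available, so none of these
numbers is ever a fit target.
"""

from __future__ import annotations

import pandas as pd

from .composition import SL_COMPOUNDS, SLProfile

# g/100 g db per compound, in SL_COMPOUNDS order, plus the printed total.
_COMPOSITION = {
    "70/30": ([1.094, 0.554, 0.328, 1.129, 1.291, 0.083], 4.479),
    "50/50": ([0.809, 0.515, 0.285, 0.946, 0.045, 0.057], 3.457),
    "CPC 70/30 I": ([0.030, 0.671, 0.323, 0.100, 1.303, 0.120], 4.267),
    "CPC 70/30 II": ([1.612, 0.236, 0.175, 1.830, 0.418, 0.007], 4.278),
    "CPC 50/50 I": ([0.042, 0.645, 0.311, 0.105, 0.085, 0.088], 2.041),
    "CPC 50/50 II": ([1.188, 0.273, 0.125, 1.359, 0.004, 0.006], 2.955),
}


def sl_profiles() -> list[SLProfile]:
    """The six extract composition profiles with their printed totals."""
    return [
        SLProfile(label=label,
                  concentrations=dict(zip(SL_COMPOUNDS, values)),
                  stated_total=total)
        for label, (values, total) in _COMPOSITION.items()
    ]


def thermodynamic_table() -> pd.DataFrame:
    """Published per-inhibitor ITC parameters.

    Columns: dh_kj_mol, dg_kj_mol, ds_j_mol_k, kd_um, ka_e3_per_m
    (K_A in 10^3 L/mol as printed), ia_percent, ic50_um, ki_um.
    """
    rows = {
        "lactucin":      [-166.93, -23.41, -262.62, 29.90, 33.44, 26.23, 3.11, 1.12],
        "lactucopicrin": [-74.45, -22.41, -262.27, 169.00, 5.92, 79.07, 1.74, 1.32],
        "CPC 70/30 I":   [-69.93, -20.94, -212.14, 147.00, 6.81, 91.19, 1.65, 1.16],
        "CPC 70/30 II":  [-58.74, -22.24, -263.68, 299.02, 3.34, 98.41, 1.55, 1.18],
        "CPC 50/50 I":   [-58.49, -22.99, -289.61, 180.01, 5.56, 98.61, 1.51, 1.43],
        "CPC 50/50 II":  [-57.72, -23.43, -261.92, 134.02, 7.46, 98.26, 1.53, 1.12],
    }
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["dh_kj_mol", "dg_kj_mol", "ds_j_mol_k", "kd_um",
                 "ka_e3_per_m", "ia_percent", "ic50_um", "ki_um"],
    ).rename_axis("inhibitor")


#: Published Michaelis constant for ACh hydrolysis by AChE, µmol/L —
#: used as a realistic simulation ground truth only.
KM_ACH_UM = 48.50
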