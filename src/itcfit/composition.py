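"""Sesquiterpene-lactone (SL) quantification arithmetic: calibration
curves, extract composition totals and lactucin-equivalent molar doses.

Works on per-extract composition profiles (g per 100 g dry basis for the
six SLs quantified in chicory-root extracts) and on calibration standards
in the 0.01–1.0 mg/mL range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError
from .units import LACTUCIN_MOLAR_MASS

__all__ = [
    "SL_COMPOUNDS",
    "CalibrationCurve",
    "SLProfile",
    "fit_calibration",
    "total_sls",
    "audit_profiles",
    "lactucin_equivalent_micromol",
]

SL_COMPOUNDS = (
    "8-deoxylactucin",
    "lactucin",
    "11(S),13-dihydrolactucin",
    "8-deoxylactucin oxalate",
    "lactucopicrin",
    "11(Z),13-dihydrolactucopicrin",
)

CALIBRATION_RANGE_MG_ML = (0.01, 1.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS response line for one analyte over the calibration range."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    range_mg_ml: tuple[float, float] = CALIBRATION_RANGE_MG_ML

    def quantify(self, response: float) -> tuple[float, bool]:
        """Concentration (mg/mL) for a response; flags out-of-range values."""
        conc = (response - self.intercept) / self.slope
        in_range = self.range_mg_ml[0] <= conc <= self.range_mg_ml[1]
        return conc, not in_range


@dataclass(frozen=True)
class SLProfile:
    """Per-compound concentrations (g/100 g db) for one extract.

    ``stated_total`` is the total as printed in the source table; the
    ``consistent`` property checks it against the component sum at 3
    decimals (the table's precision).
    """

    label: str
    concentrations: dict[str, float]
    stated_total: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")

    @property
    def component_sum(self) -> float:
        return round(sum(self.concentrations.values()), 3)

    @property
    def consistent(self) -> bool:
        if self.stated_total is None:
            return True
        return abs(self.component_sum - self.stated_total) < 5e-4


def fit_calibration(standards: pd.DataFrame | list[tuple[float, float]],
                    analyte: str = "") -> CalibrationCurve:
    """Ordinary least-squares calibration line from (concentration mg/mL,
    response) standards; needs >= 2 distinct concentrations."""
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("standards must be (concentration, response) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise FitError("need at least 2 distinct standard concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(analyte=analyte, slope=float(slope),
                            intercept=float(intercept), r_squared=r2)


def total_sls(profile: SLProfile) -> float:
    """Sum of the six SL components, g/100 g db, at 3 decimals."""
    missing = [c for c in SL_COMPOUNDS if c not in profile.concentrations]
    if missing:
        raise FitError(f"profile {profile.label!r} missing components: "
                       f"{missing}")
    return round(sum(profile.concentrations[c] for c in SL_COMPOUNDS), 3)


def audit_profiles(profiles: list[SLProfile]) -> pd.DataFrame:
    """Consistency audit: recompute each total and flag profiles whose
    stated total differs from the component sum at 3 decimals."""
    rows = []
    for p in profiles:
        total = total_sls(p)
        rows.append({
            "extract": p.label,
            "component_sum": total,
            "stated_total": p.stated_total,
            "consistent": p.stated_total is None
                          or abs(total - p.stated_total) < 5e-4,
        })
    return pd.DataFrame(rows)


def lactucin_equivalent_micromol(
    extract_mass_g: float,
    sl_mass_fraction: float,
    molar_mass_g_mol: float = LACTUCIN_MOLAR_MASS,
) -> float:
    """Molar SL dose of an extract, expressed as lactucin equivalents.

    µmol = mass (g) × SL mass fraction / molar mass (g/mol) × 1e6.
    """
    if extract_mass_g <= 0 or molar_mass_g_mol <= 0 or sl_mass_fraction < 0:
        raise ValueError("mass and molar mass must be positive, fraction >= 0")
    return extract_mass_g * sl_mass_fraction / molar_mass_g_mol * 1e6
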