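"""Corrected inhibitory activity (IA%) and IC50.

The IA statistic compares the heat of enzymatic substrate hydrolysis with
and without inhibitor, after subtracting the non-catalytic contributions
measured in control titrations: the enzyme–inhibitor interaction heat and
the dilution heats of substrate and inhibitor.

With the five ledger terms (all molar heats, kJ/mol):

    corrected uninhibited   Q0 = H_hyd − H_dilS
    corrected inhibited     Qi = H_hyd_inh − H_EI − H_dilS − H_dilI

    IA% = (Q0 − Qi) / Q0 × 100

IA is invariant under a common rescaling of all five heats, is 0 when the
inhibitor leaves hydrolysis unchanged and 100 when the corrected inhibited
heat vanishes.  Values outside [0, 100] are reported, not clipped (negative
IA = apparent activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import BracketingError, FitError, LedgerError, ModelOrientationError

__all__ = [
    "HeatLedger",
    "InhibitionResult",
    "inhibitory_activity",
    "ic50",
    "ic50_cheng_prusoff",
]


@dataclass(frozen=True)
class HeatLedger:
    """The five heat terms feeding IA% (kJ/mol unless noted; any common
    unit works — the statistic is scale-free).

    h_hyd: uninhibited hydrolysis heat; h_hyd_inh: hydrolysis heat with the
    inhibitor present (includes every heat source of that run);
    h_ei: enzyme–inhibitor interaction heat measured in the inhibition
    test; h_dil_s / h_dil_i: substrate and inhibitor dilution heats.
    """

    h_hyd: float
    h_hyd_inh: float
    h_ei: float
    h_dil_s: float
    h_dil_i: float

    def __post_init__(self) -> None:
        vals = (self.h_hyd, self.h_hyd_inh, self.h_ei, self.h_dil_s,
                self.h_dil_i)
        if not all(np.isfinite(vals)):
            raise LedgerError("all ledger heats must be finite")


@dataclass(frozen=True)
class InhibitionResult:
    ia_percent: float
    ic50_um: float | None
    method: str
    out_of_range: bool = False


def inhibitory_activity(ledger: HeatLedger) -> InhibitionResult:
    """Corrected inhibitory activity, percent.

    The denominator is the corrected uninhibited heat (H_hyd − H_dilS);
    a zero denominator is an error.
    """
    q0 = ledger.h_hyd - ledger.h_dil_s
    if q0 == 0:
        raise LedgerError("zero corrected uninhibited heat: IA undefined")
    qi = ledger.h_hyd_inh - ledger.h_ei - ledger.h_dil_s - ledger.h_dil_i
    ia = (q0 - qi) * 100.0 / q0
    return InhibitionResult(ia_percent=ia, ic50_um=None, method="ledger",
                            out_of_range=not (0.0 <= ia <= 100.0))


def _loglogistic(c, top, log_ec50, hill):
    c = np.asarray(c, dtype=float)
    return top / (1.0 + np.exp(hill * (log_ec50 - np.log(c))))


def ic50(curve: np.ndarray | list[tuple[float, float]]) -> InhibitionResult:
    """IC50 from an (inhibitor concentration µmol/L, IA %) dose series.

    Fits a log-logistic curve with floor fixed at 0 and ceiling floated
    (capped at 100); IC50 is the concentration where the fitted curve
    crosses IA = 50, which requires the data to bracket 50%.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("curve must be (concentration, IA) pairs")
    c, ia = arr[:, 0], arr[:, 1]
    if arr.shape[0] < 4:
        raise FitError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise FitError("concentrations must be positive")
    order = np.argsort(c)
    c, ia = c[order], ia[order]
    if ia.min() > 50.0 or ia.max() < 50.0:
        raise BracketingError("dose series does not bracket IA = 50%")
    # orientation: IA must rise with inhibitor concentration
    slope = np.polyfit(np.log(c), ia, 1)[0]
    if slope < 0:
        raise ModelOrientationError(
            "IA decreases with concentration: not an inhibition curve")

    p0 = [min(max(ia.max(), 50.1), 100.0),
          float(np.log(np.interp(50.0, ia, c))), 1.0]
    try:
        popt, _ = curve_fit(_loglogistic, c, ia, p0=p0,
                            bounds=([10.0, -np.inf, 0.05],
                                    [100.0, np.inf, 20.0]), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"log-logistic fit failed: {exc}") from exc
    top, log_ec50, hill = popt
    if top <= 50.0:
        raise BracketingError("fitted ceiling at or below 50%: IC50 undefined")
    # concentration where top/(1+(ec50/c)^hill) = 50
    ic = float(np.exp(log_ec50) * (50.0 / (top - 50.0)) ** (1.0 / hill))
    return InhibitionResult(ia_percent=float(ia.max()), ic50_um=ic,
                            method="log-logistic dose curve")


def ic50_cheng_prusoff(ki_um: float, s_um: float, km_um: float) -> float:
    """Competitive-inhibition cross-check: IC50 = Ki·(1 + S/Km)."""
    if ki_um <= 0 or s_um < 0 or km_um <= 0:
        raise ValueError("Ki, Km must be > 0 and S >= 0")
    return ki_um * (1.0 + s_um / km_um)
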