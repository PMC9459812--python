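"""Michaelis–Menten kinetics from ITC-derived rate data: Km, Vmax and the
competitive inhibition constant Ki.

Rates come from :func:`itcfit.thermogram.heat_flow_to_rate`; the saturation
curve is read as the pseudo-steady-state rate shortly after each substrate
injection (median of a short post-injection window), matching the
multiple-injection ITC kinetics protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError
from .thermogram import Thermogram, heat_flow_to_rate

__all__ = [
    "KineticFit",
    "mm_rate",
    "competitive_rate",
    "fit_km",
    "fit_ki",
    "extract_rate_points",
]


@dataclass(frozen=True)
class KineticFit:
    """Fitted kinetic parameters with asymptotic standard errors."""

    km_um: float
    vmax_um_s: float
    ki_um: float | None
    se_km_um: float
    se_vmax_um_s: float
    se_ki_um: float | None
    residual_norm: float
    converged: bool
    extrapolated: bool = False  # max S below Km: Vmax poorly constrained

    def __post_init__(self) -> None:
        if self.km_um <= 0 or self.vmax_um_s <= 0:
            raise ValueError("Km and Vmax must be > 0")
        if self.ki_um is not None and self.ki_um <= 0:
            raise ValueError("Ki must be > 0 when present")


def mm_rate(s_um, vmax_um_s: float, km_um: float):
    """Michaelis–Menten rate v = Vmax·S/(Km + S)."""
    if km_um <= 0:
        raise ValueError("Km must be > 0")
    s = np.asarray(s_um, dtype=float)
    return vmax_um_s * s / (km_um + s)


def competitive_rate(s_um, i_um, vmax_um_s: float, km_um: float, ki_um: float):
    """Competitive-inhibition rate v = Vmax·S/(Km·(1 + I/Ki) + S)."""
    if km_um <= 0 or ki_um <= 0:
        raise ValueError("Km and Ki must be > 0")
    s = np.asarray(s_um, dtype=float)
    i = np.asarray(i_um, dtype=float)
    return vmax_um_s * s / (km_um * (1.0 + i / ki_um) + s)


def fit_km(points: pd.DataFrame) -> KineticFit:
    """Fit (Km, Vmax) to uninhibited rate points.

    ``points`` needs columns ``S_um`` and ``v_um_s`` (column ``I_um``, if
    present, must be all zero).  Warns when the data do not reach
    half-saturation (max S < fitted Km).
    """
    s = points["S_um"].to_numpy(dtype=float)
    v = points["v_um_s"].to_numpy(dtype=float)
    if "I_um" in points and np.any(points["I_um"].to_numpy() != 0):
        raise FitError("fit_km expects uninhibited points (I = 0)")
    if s.size < 4:
        raise FitError("need at least 4 rate points")
    if np.ptp(s) == 0:
        raise FitError("degenerate data: all substrate concentrations equal")

    v90 = np.quantile(v, 0.9)
    p0 = [max(2.0 * v90, 1e-9), max(np.median(s), 1e-3)]
    try:
        popt, pcov = curve_fit(
            lambda x, vmax, km: mm_rate(x, vmax, km), s, v, p0=p0,
            bounds=([1e-12, 1e-6], [np.inf, np.inf]), maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise FitError(f"Km fit did not converge: {exc}") from exc
    vmax, km = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    extrapolated = bool(np.max(s) < km)
    if extrapolated:
        warnings.warn("max substrate concentration below fitted Km: "
                      "Vmax is an extrapolation", stacklevel=2)
    resid = v - mm_rate(s, vmax, km)
    return KineticFit(km_um=km, vmax_um_s=vmax, ki_um=None,
                      se_km_um=float(se[1]), se_vmax_um_s=float(se[0]),
                      se_ki_um=None,
                      residual_norm=float(np.linalg.norm(resid)),
                      converged=True, extrapolated=extrapolated)


def fit_ki(points: pd.DataFrame, uninhibited: KineticFit) -> KineticFit:
    """Fit Ki alone under the competitive model, Km and Vmax held fixed.

    ``points`` needs columns ``S_um``, ``v_um_s`` and ``I_um`` (> 0).
    Systematically faster-than-uninhibited rates trigger a model-mismatch
    warning.
    """
    s = points["S_um"].to_numpy(dtype=float)
    v = points["v_um_s"].to_numpy(dtype=float)
    if "I_um" not in points:
        raise FitError("fit_ki needs an I_um column")
    i = points["I_um"].to_numpy(dtype=float)
    if np.all(i == 0):
        raise FitError("fit_ki expects inhibited points (I > 0)")
    km, vmax = uninhibited.km_um, uninhibited.vmax_um_s
    v_pred0 = mm_rate(s, vmax, km)
    if np.median(v - v_pred0) > 0:
        warnings.warn("inhibited rates exceed the uninhibited prediction: "
                      "competitive model may not apply", stacklevel=2)
    # log-parameterised 1-D fit keeps Ki positive
    try:
        popt, pcov = curve_fit(
            lambda x, log_ki: competitive_rate(x[0], x[1], vmax, km,
                                               np.exp(log_ki)),
            (s, i), v, p0=[np.log(np.median(i[i > 0]))], maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as exc:
        raise FitError(f"Ki fit did not converge: {exc}") from exc
    ki = float(np.exp(popt[0]))
    se_ki = float(np.sqrt(max(pcov[0, 0], 0.0))) * ki
    resid = v - competitive_rate(s, i, vmax, km, ki)
    return KineticFit(km_um=km, vmax_um_s=vmax, ki_um=ki,
                      se_km_um=uninhibited.se_km_um,
                      se_vmax_um_s=uninhibited.se_vmax_um_s, se_ki_um=se_ki,
                      residual_norm=float(np.linalg.norm(resid)),
                      converged=True)


def extract_rate_points(
    tg: Thermogram,
    dh_app_kj_mol: float,
    tau_s: float = 0.0,
    inhibitor_um: float = 0.0,
    window_s: tuple[float, float] = (8.0, 28.0),
) -> pd.DataFrame:
    """Pseudo-steady-state (S, v) pairs, one per substrate injection.

    For each injection the rate is the median of v(t) over
    ``window_s`` = (t0, t1) seconds after the injection start (past the
    instrument rise, before appreciable depletion), paired with the median
    reconstructed substrate concentration over the same window.  The
    in-cell inhibitor concentration is tracked through the per-injection
    dilution factor.

    Returns a DataFrame with columns ``S_um``, ``v_um_s``, ``I_um``.
    """
    rates = heat_flow_to_rate(tg, dh_app_kj_mol, tau_s=tau_s)
    t = rates["time_s"].to_numpy()
    out = []
    i_cur = inhibitor_um
    for inj in tg.setup.injections:
        x = inj.volume_ul / tg.setup.cell_volume_ul
        i_cur *= (1 - x / 2) / (1 + x / 2)
        mask = (t >= inj.start_s + window_s[0]) & (t < inj.start_s + window_s[1])
        if not mask.any():
            continue
        out.append({
            "S_um": float(rates["S_um"][mask].median()),
            "v_um_s": float(rates["v_um_s"][mask].median()),
            "I_um": i_cur,
        })
    return pd.DataFrame(out)
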