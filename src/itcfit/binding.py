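"""Single-site binding isotherm: displacement ledger, predicted injection
heats, nonlinear fitting and thermodynamic bookkeeping.

Model
-----
For ``n`` identical independent sites on a macromolecule at total in-cell
concentration M, total ligand X and dissociation constant K_D, the bound
ligand concentration solves the quadratic

    B = ((X + nM + K_D) - sqrt((X + nM + K_D)^2 - 4 n M X)) / 2

and the heat of injection i is the enthalpy times the *increment* of bound
material in the cell, after accounting for the dilution of previously bound
complex by the injection itself:

    q_i = dH * V0 * (B_i - B_{i-1} * f_i)

with f_i the per-injection displacement dilution factor.

Displacement ledger
-------------------
The cell is always full; injecting dV displaces dV of (mixed) cell content.
Using the mid-displacement (trapezoidal) mole balance, an injection of dV
into V0 dilutes every pre-existing species by

    f = (1 - dV/(2 V0)) / (1 + dV/(2 V0))

and credits the injected ligand at c_syr * (dV/V0) / (1 + dV/(2 V0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ScheduleError
from .experiment import ExperimentSetup
from .units import R_GAS, kj_to_ucal

__all__ = [
    "BindingParams",
    "BindingFit",
    "CellLedger",
    "displacement_ledger",
    "expected_injection_heats",
    "fit_single_site",
    "derive_thermodynamics",
]


@dataclass(frozen=True)
class BindingParams:
    """Ground-truth or fitted single-site parameters.

    n: sites per macromolecule; kd_um: dissociation constant, µmol/L;
    dh_kj_mol: binding enthalpy, kJ per mole of ligand bound.
    """

    n: float
    kd_um: float
    dh_kj_mol: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("stoichiometry n must be > 0")
        if self.kd_um <= 0:
            raise ValueError("K_D must be > 0")
        if not math.isfinite(self.dh_kj_mol):
            raise ValueError("dH must be finite")


@dataclass(frozen=True)
class CellLedger:
    """Per-injection in-cell totals after displacement.

    All arrays have one entry per injection; index 0 is the state after the
    first injection.  ``dilution`` holds the per-injection factor f_i applied
    to pre-existing species.
    """

    macromolecule_um: np.ndarray
    ligand_um: np.ndarray
    dilution: np.ndarray
    injected_moles: np.ndarray  # moles of titrant delivered per injection

    def molar_ratio(self) -> np.ndarray:
        """In-cell ligand:macromolecule ratio after each injection."""
        return self.ligand_um / self.macromolecule_um


def displacement_ledger(setup: ExperimentSetup) -> CellLedger:
    """Track in-cell concentrations through a titration in a full cell.

    Applies the mid-displacement rule per injection: pre-existing species
    dilute by f = (1-x/2)/(1+x/2) with x = dV/V0, injected ligand is
    credited at c_syr * x / (1 + x/2).
    """
    v0 = setup.cell_volume_ul
    m = setup.cell_concentration_um
    x_lig = 0.0
    c_syr = setup.syringe_concentration_um

    macro, lig, dil, moles = [], [], [], []
    for inj in setup.injections:
        dv = inj.volume_ul
        if dv >= v0:
            raise ScheduleError("injection volume must be smaller than the cell")
        x = dv / v0
        f = (1 - x / 2) / (1 + x / 2)
        m *= f
        x_lig = x_lig * f + c_syr * x / (1 + x / 2)
        macro.append(m)
        lig.append(x_lig)
        dil.append(f)
        moles.append(c_syr * 1e-6 * dv * 1e-6)  # mol = (mol/L) * L
    return CellLedger(
        macromolecule_um=np.asarray(macro),
        ligand_um=np.asarray(lig),
        dilution=np.asarray(dil),
        injected_moles=np.asarray(moles),
    )


def bound_concentration(
    x_total_um: np.ndarray, m_total_um: np.ndarray, params: BindingParams
) -> np.ndarray:
    """Bound-ligand concentration from the single-site quadratic (µmol/L)."""
    x = np.asarray(x_total_um, dtype=float)
    nm = params.n * np.asarray(m_total_um, dtype=float)
    s = x + nm + params.kd_um
    disc = s * s - 4.0 * nm * x
    # disc = (x - nm + K)^2 + 4*nm*K >= 0 for valid inputs
    if np.any(disc < 0):
        raise AssertionError("negative discriminant: invalid concentrations")
    return 0.5 * (s - np.sqrt(disc))


def expected_injection_heats(
    params: BindingParams, setup: ExperimentSetup
) -> np.ndarray:
    """Closed-form per-injection heats (µcal) for a single-site titration.

    q_i = dH * V0 * (B_i - B_{i-1} * f_i): the newly bound material, with
    the previously bound complex first diluted by the displacement factor of
    injection i.  Exothermic binding (dH < 0) gives negative heats.
    """
    ledger = displacement_ledger(setup)
    b = bound_concentration(ledger.ligand_um, ledger.macromolecule_um, params)
    b_prev = np.concatenate(([0.0], b[:-1]))
    delta_um = b - b_prev * ledger.dilution
    # kJ = (kJ/mol) * L * (mol/L);  µmol/L -> mol/L is 1e-6
    q_kj = params.dh_kj_mol * setup.cell_volume_l * delta_um * 1e-6
    return kj_to_ucal(q_kj)


@dataclass(frozen=True)
class BindingFit:
    """Fit result mirroring one thermodynamic-table row.

    Invariants maintained by construction: ka_per_m * kd (in mol/L) == 1,
    and dg_kj_mol == dh_kj_mol - T * ds_j_mol_k / 1000 exactly as stored.
    """

    params: BindingParams
    ka_per_m: float
    dg_kj_mol: float
    ds_j_mol_k: float
    temperature_k: float
    se_n: float
    se_kd_um: float
    se_dh_kj_mol: float
    offset_ucal: float
    se_offset_ucal: float
    residual_norm: float
    n_iterations: int
    converged: bool
    c_value: float
    weak_saturation: bool
    n_fixed: bool


def derive_thermodynamics(
    kd_um: float, dh_kj_mol: float, temperature_k: float
) -> tuple[float, float, float]:
    """Derive (K_A, ΔG, ΔS) from K_D and ΔH at temperature T.

    K_A = 1/K_D (L/mol, unit-consistent reciprocal); ΔG = -R T ln(K_A c°)
    with c° = 1 mol/L; ΔS = (ΔH - ΔG)/T so that ΔG = ΔH - TΔS holds exactly.

    Returns (ka_per_m, dg_kj_mol, ds_j_mol_k).
    """
    if kd_um <= 0 or temperature_k <= 0:
        raise ValueError("K_D and T must be positive")
    kd_m = kd_um * 1e-6
    ka = 1.0 / kd_m
    dg_kj = -R_GAS * temperature_k * math.log(ka) / 1000.0
    ds = (dh_kj_mol - dg_kj) * 1000.0 / temperature_k
    return ka, dg_kj, ds


def _c_value(params: BindingParams, setup: ExperimentSetup) -> float:
    """Wiseman c parameter n[M]/K_D; identifiability is best in [1, 1000]."""
    return params.n * setup.cell_concentration_um / params.kd_um


def fit_single_site(
    q_obs_ucal: np.ndarray,
    setup: ExperimentSetup,
    fix_n: float | None = None,
    fit_offset: bool = True,
    init: BindingParams | None = None,
) -> BindingFit:
    """Least-squares fit of the single-site model to per-injection heats.

    Parameters
    ----------
    q_obs_ucal : observed per-injection heats, µcal (one per injection).
    fix_n : if given, stoichiometry is held at this value (standard for
        low-c titrations where n is not identifiable).
    fit_offset : include a constant per-injection heat (µcal) absorbing
        un-subtracted dilution heat; ON by default.
    init : optional starting parameters; otherwise heuristic initialisation
        (dH from the first molar heat, K_D from half-total-heat, n = 1).
    """
    q = np.asarray(q_obs_ucal, dtype=float)
    if q.size < 5:
        raise FitError("need at least 5 injections to fit three parameters")
    if len(setup.injections) != q.size:
        raise FitError("heats and injection schedule length mismatch")
    if np.allclose(q, 0.0):
        raise FitError("all-zero heats: binding parameters not identifiable")

    ledger = displacement_ledger(setup)

    if init is None:
        # dH from the first injection's molar heat (kJ/mol of injectant)
        q1_kj = q[0] / kj_to_ucal(1.0)
        dh0 = q1_kj / ledger.injected_moles[0]
        if dh0 == 0:
            dh0 = -10.0
        # K_D near the in-cell ligand concentration at half cumulative heat
        cum = np.cumsum(q)
        half = np.searchsorted(np.abs(cum), 0.5 * np.abs(cum[-1]))
        kd0 = float(ledger.ligand_um[min(half, q.size - 1)])
        kd0 = min(max(kd0, 1e-3), 1e6)
        init = BindingParams(n=1.0 if fix_n is None else fix_n, kd_um=kd0,
                             dh_kj_mol=dh0)

    log_kd0 = math.log(min(max(init.kd_um, 1e-3), 1e6))

    def unpack(theta: np.ndarray) -> tuple[BindingParams, float]:
        i = 0
        if fix_n is None:
            n = theta[i]; i += 1
        else:
            n = fix_n
        kd = math.exp(theta[i]); i += 1
        dh = theta[i]; i += 1
        offset = theta[i] if fit_offset else 0.0
        return BindingParams(n=n, kd_um=kd, dh_kj_mol=dh), offset

    def residuals(theta: np.ndarray) -> np.ndarray:
        p, offset = unpack(theta)
        return expected_injection_heats(p, setup) + offset - q

    theta0, lo, hi = [], [], []
    if fix_n is None:
        theta0.append(init.n); lo.append(0.1); hi.append(10.0)
    theta0.append(log_kd0); lo.append(math.log(1e-3)); hi.append(math.log(1e6))
    theta0.append(init.dh_kj_mol); lo.append(-np.inf); hi.append(np.inf)
    if fit_offset:
        theta0.append(0.0); lo.append(-np.inf); hi.append(np.inf)

    sol = least_squares(residuals, theta0, bounds=(lo, hi), xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    params, offset = unpack(sol.x)
    converged = bool(sol.success)

    # asymptotic covariance from the Jacobian at the optimum
    dof = max(q.size - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(sol.x.size, np.nan)
        converged = False

    i = 0
    if fix_n is None:
        se_n = float(se[i]); i += 1
    else:
        se_n = 0.0
    se_kd = float(se[i]) * params.kd_um  # delta method for log-K_D
    i += 1
    se_dh = float(se[i]); i += 1
    se_off = float(se[i]) if fit_offset else 0.0

    ka, dg, ds = derive_thermodynamics(params.kd_um, params.dh_kj_mol,
                                       setup.temperature_k)
    c = _c_value(params, setup)
    return BindingFit(
        params=params, ka_per_m=ka, dg_kj_mol=dg, ds_j_mol_k=ds,
        temperature_k=setup.temperature_k,
        se_n=se_n, se_kd_um=se_kd, se_dh_kj_mol=se_dh,
        offset_ucal=offset, se_offset_ucal=se_off,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        n_iterations=int(sol.nfev), converged=converged,
        c_value=c, weak_saturation=not (1.0 <= c <= 1000.0),
        n_fixed=fix_n is not None,
    )
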