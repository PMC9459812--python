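"""Synthetic thermogram generation with known ground truth.

Three experiment kinds are emulated, matching an enzyme-inhibition ITC
campaign on a 200 µL cell:

* **binding titration** — ligand injected into the macromolecule solution;
  each injection releases the closed-form single-site heat;
* **dilution control** — ligand injected into buffer; each injection
  contributes a constant dilution heat;
* **substrate hydrolysis** — substrate injected onto the enzyme (optionally
  with a competitive inhibitor present); the trace follows the
  Michaelis–Menten progress curve between injections.

The ideal power trace is smeared by a first-order (single-exponential)
instrument response and overlaid with white Gaussian noise plus optional
linear baseline drift.  Exothermic events are negative.  All randomness is
seeded through :class:`~itcfit.experiment.NoiseModel`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .binding import BindingParams, expected_injection_heats
from .errors import ItcError
from .experiment import ExperimentSetup, InstrumentModel, NoiseModel
from .thermogram import Thermogram
from .units import kj_to_ucal

__all__ = [
    "KineticTruth",
    "simulate_binding_titration",
    "simulate_dilution_control",
    "simulate_hydrolysis",
]

DEFAULT_SAMPLE_RATE_HZ = 1.0


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth hydrolysis kinetics for the simulator.

    km_um, vmax_um_s: Michaelis–Menten parameters; ki_um: competitive
    inhibition constant (None = no inhibitor term); inhibitor_um: in-cell
    inhibitor concentration at t=0; dh_app_kj_mol: apparent molar enthalpy
    of hydrolysis (positive = endothermic signal).
    """

    km_um: float
    vmax_um_s: float
    ki_um: float | None = None
    inhibitor_um: float = 0.0
    dh_app_kj_mol: float = 20.0

    def __post_init__(self) -> None:
        if self.km_um <= 0 or self.vmax_um_s < 0:
            raise ValueError("Km must be > 0 and Vmax >= 0")
        if self.ki_um is not None and self.ki_um <= 0:
            raise ValueError("Ki must be > 0 when present")


def _time_grid(setup: ExperimentSetup, sample_rate_hz: float,
               tail_s: float) -> np.ndarray:
    last = setup.injections[-1]
    t_end = last.start_s + tail_s
    n = int(round(t_end * sample_rate_hz)) + 1
    return np.arange(n) / sample_rate_hz


def _smear(power: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """Exact first-order (RC) response with unit DC gain; preserves area."""
    if tau_s == 0:
        return power
    a = np.exp(-dt / tau_s)
    out = np.empty_like(power)
    acc = 0.0
    for k, x in enumerate(power):
        acc = a * acc + (1.0 - a) * x
        out[k] = acc
    return out


def _add_noise(power: np.ndarray, t: np.ndarray, noise: NoiseModel) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    out = power + noise.baseline_drift_ucal_s2 * t
    if noise.power_sigma_ucal_s > 0:
        out = out + rng.normal(0.0, noise.power_sigma_ucal_s, size=t.size)
    return out


def _check_schedule_density(setup: ExperimentSetup,
                            instrument: InstrumentModel) -> None:
    starts = [inj.start_s for inj in setup.injections]
    spacings = np.diff(starts)
    if spacings.size and instrument.response_tau_s > 0:
        if np.min(spacings) < 5.0 * instrument.response_tau_s:
            warnings.warn(
                "injection spacing shorter than 5*tau: peaks may overlap",
                stacklevel=2)


def _pulse_train(
    q_ucal: np.ndarray, t: np.ndarray, setup: ExperimentSetup
) -> np.ndarray:
    """Ideal power: heat q_i released uniformly over injection i's duration.

    Samples describe a piecewise-linear signal that is zero at the
    injection-start sample and rises over one step, so the trapezoidal
    integral over the injection window equals q_i exactly.
    """
    dt = t[1] - t[0]
    power = np.zeros_like(t)
    for q, inj in zip(q_ucal, setup.injections):
        mask = (t > inj.start_s) & (t <= inj.start_s + inj.duration_s)
        if not mask.any():  # duration shorter than one sample: lump it
            k = int(np.searchsorted(t, inj.start_s, side="right"))
            power[min(k, t.size - 1)] += q / dt
        else:
            power[mask] += q / (mask.sum() * dt)
    return power


def _ground_truth_meta(**kwargs) -> dict:
    return {k: json.dumps(v) if not isinstance(v, str) else v
            for k, v in kwargs.items()}


def simulate_binding_titration(
    truth: BindingParams,
    setup: ExperimentSetup,
    instrument: InstrumentModel = InstrumentModel(),
    noise: NoiseModel = NoiseModel(),
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    tail_s: float = 180.0,
) -> Thermogram:
    """Simulate a ligand-into-macromolecule titration.

    Each injection's pulse carries exactly the closed-form single-site heat
    for the ground-truth parameters; the trace is the smeared, noised pulse
    train.  Ground truth is recorded in the provenance metadata.
    """
    _check_schedule_density(setup, instrument)
    t = _time_grid(setup, sample_rate_hz, tail_s)
    q = expected_injection_heats(truth, setup)
    power = _pulse_train(q, t, setup)
    power = _smear(power, t[1] - t[0], instrument.response_tau_s)
    power = _add_noise(power, t, noise)
    meta = _ground_truth_meta(
        kind="binding", n=truth.n, kd_um=truth.kd_um,
        dh_kj_mol=truth.dh_kj_mol, tau_s=instrument.response_tau_s,
        sigma=noise.power_sigma_ucal_s, seed=noise.seed)
    return Thermogram(t, power, setup, meta)


def simulate_dilution_control(
    setup: ExperimentSetup,
    per_injection_dilution_heat_ucal: float,
    instrument: InstrumentModel = InstrumentModel(),
    noise: NoiseModel = NoiseModel(),
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    tail_s: float = 180.0,
) -> Thermogram:
    """Simulate titrant injected into the cell without the enzyme: every
    injection releases the same constant dilution heat."""
    _check_schedule_density(setup, instrument)
    t = _time_grid(setup, sample_rate_hz, tail_s)
    q = np.full(len(setup.injections), per_injection_dilution_heat_ucal)
    power = _pulse_train(q, t, setup)
    power = _smear(power, t[1] - t[0], instrument.response_tau_s)
    power = _add_noise(power, t, noise)
    meta = _ground_truth_meta(
        kind="dilution", q_dil_ucal=per_injection_dilution_heat_ucal,
        tau_s=instrument.response_tau_s, sigma=noise.power_sigma_ucal_s,
        seed=noise.seed)
    return Thermogram(t, power, setup, meta)


def _rate(s_um: float, i_um: float, truth: KineticTruth) -> float:
    km_app = truth.km_um
    if truth.ki_um is not None:
        km_app = truth.km_um * (1.0 + i_um / truth.ki_um)
    return truth.vmax_um_s * s_um / (km_app + s_um)


def simulate_hydrolysis(
    truth: KineticTruth,
    setup: ExperimentSetup,
    instrument: InstrumentModel = InstrumentModel(),
    noise: NoiseModel = NoiseModel(),
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    tail_s: float = 180.0,
    rtol: float = 1e-9,
) -> Thermogram:
    """Simulate substrate hydrolysis under the calorimeter.

    Between injections the substrate follows d[S]/dt = -v([S]) with
    v = Vmax·S/(Km·(1+[I]/Ki) + S); each injection dilutes S and I through
    the displacement ledger and credits fresh substrate.  Power is
    dH_app·V0·v(t) in µcal/s, then smeared and noised.

    The internal (noise-free, unsmeared) rate trace is stored in the
    returned thermogram's provenance as ``v_um_s`` for round-trip tests.
    """
    _check_schedule_density(setup, instrument)
    t = _time_grid(setup, sample_rate_hz, tail_s)
    v0_ul = setup.cell_volume_ul
    c_syr = setup.syringe_concentration_um

    s_cur, i_cur = 0.0, truth.inhibitor_um
    v_trace = np.zeros_like(t)
    s_trace = np.zeros_like(t)
    hydrolyzed_umol_l = 0.0  # cumulative, in original-cell-volume units

    events = [(inj.start_s, inj.volume_ul) for inj in setup.injections]
    events.append((t[-1] + 1.0, 0.0))
    for (start, dv), (nxt, _) in zip(events, events[1:]):
        if dv > 0:
            x = dv / v0_ul
            f = (1 - x / 2) / (1 + x / 2)
            s_cur = s_cur * f + c_syr * x / (1 + x / 2)
            i_cur = i_cur * f
        seg = (t >= start) & (t < nxt)
        t_seg = t[seg]
        seg_end = min(nxt, t[-1] + 1.0)
        t_eval = np.append(t_seg, seg_end)  # last entry advances the state
        sol = solve_ivp(
            lambda _t, y, i=i_cur: [-_rate(y[0], i, truth)],
            (start, seg_end), [s_cur],
            t_eval=t_eval, rtol=rtol, atol=1e-12, method="LSODA",
        )
        if not sol.success or np.any(sol.y[0] < -1e-9):
            raise ItcError("hydrolysis integrator failed (negative [S])")
        s_vals = np.clip(sol.y[0], 0.0, None)
        s_trace[seg] = s_vals[:-1]
        v_trace[seg] = [_rate(s, i_cur, truth) for s in s_vals[:-1]]
        hydrolyzed_umol_l += s_cur - float(s_vals[-1])
        s_cur = float(s_vals[-1])

    # P [µcal/s] = dH_app [kJ/mol] * V0 [L] * v [mol/L/s]
    power = kj_to_ucal(truth.dh_app_kj_mol * setup.cell_volume_l * v_trace * 1e-6)
    power = _smear(power, t[1] - t[0], instrument.response_tau_s)
    power = _add_noise(power, t, noise)
    meta = _ground_truth_meta(
        kind="hydrolysis", km_um=truth.km_um, vmax_um_s=truth.vmax_um_s,
        ki_um=truth.ki_um, inhibitor_um=truth.inhibitor_um,
        dh_app_kj_mol=truth.dh_app_kj_mol, tau_s=instrument.response_tau_s,
        sigma=noise.power_sigma_ucal_s, seed=noise.seed,
        s_remaining_um=s_cur, hydrolyzed_um=hydrolyzed_umol_l)
    tg = Thermogram(t, power, setup, meta)
    object.__setattr__(tg, "_v_internal", v_trace)
    object.__setattr__(tg, "_s_internal", s_trace)
    return tg


def write_ground_truth(tg: Thermogram, path: str | Path) -> None:
    """Dump the simulator's ground-truth metadata as JSON."""
    with open(Path(path), "w") as fh:
        json.dump(tg.provenance, fh, indent=1)
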