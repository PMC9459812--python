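"""Thermogram container, plain-text I/O, baseline estimation, peak
integration and heat-flow → reaction-rate conversion.

File format
-----------
A thermogram is stored as a CSV whose first line is ``# itc-thermogram v1``,
followed by ``# key=value`` metadata lines and a ``time_s,power_ucal_per_s``
table, plus a JSON sidecar (``<stem>.setup.json``) holding the cell/syringe
loading and the injection schedule.  Power is in µcal/s with exothermic
events negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import displacement_ledger
from .errors import BaselineError, ItcError, MonotonicityError, ThermogramFormatError
from .experiment import ExperimentSetup, Injection
from .units import ucal_to_kj

__all__ = [
    "Thermogram",
    "HeatSeries",
    "read_thermogram",
    "write_thermogram",
    "estimate_baseline",
    "instrument_baseline",
    "integrate_peaks",
    "heat_flow_to_rate",
]

_HEADER = "# itc-thermogram v1"


@dataclass(frozen=True)
class Thermogram:
    """Uniformly sampled differential-power trace with its experiment setup."""

    time_s: np.ndarray
    power_ucal_s: np.ndarray
    setup: ExperimentSetup
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.power_ucal_s, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "power_ucal_s", p)
        if t.ndim != 1 or t.size < 2 or p.shape != t.shape:
            raise ThermogramFormatError("time and power must be equal-length 1-D")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise MonotonicityError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise MonotonicityError("time must be uniformly sampled")
        if not np.all(np.isfinite(p)):
            raise ThermogramFormatError("power must be finite everywhere")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def provenance_value(self, key: str):
        """Metadata value parsed back to its Python type where possible."""
        raw = self.provenance[key]
        try:
            return json.loads(raw)
        except (json.JSONDecodeError, TypeError):
            return raw


@dataclass(frozen=True)
class HeatSeries:
    """Per-injection integrated heats.

    q_ucal: raw integral of baseline-corrected power (µcal);
    q_kj_per_mol: per mole of injectant; molar_ratio: in-cell
    ligand:macromolecule ratio after the injection (displacement ledger).
    ``truncated`` flags integrals whose window was cut by the end of trace.
    """

    injection: np.ndarray
    q_ucal: np.ndarray
    q_kj_per_mol: np.ndarray
    molar_ratio: np.ndarray
    truncated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": self.injection,
                "q_ucal": self.q_ucal,
                "q_kj_per_mol": self.q_kj_per_mol,
                "molar_ratio": self.molar_ratio,
            }
        )


def _setup_to_dict(setup: ExperimentSetup) -> dict:
    return {
        "cell_volume_ul": setup.cell_volume_ul,
        "temperature_c": setup.temperature_c,
        "cell_concentration_um": setup.cell_concentration_um,
        "syringe_concentration_mm": setup.syringe_concentration_mm,
        "stir_note": setup.stir_note,
        "injections": [
            {"volume_ul": i.volume_ul, "start_s": i.start_s,
             "duration_s": i.duration_s}
            for i in setup.injections
        ],
    }


def _setup_from_dict(d: dict) -> ExperimentSetup:
    try:
        injections = tuple(
            Injection(i["volume_ul"], i["start_s"], i.get("duration_s", 4.0))
            for i in d["injections"]
        )
        return ExperimentSetup(
            cell_volume_ul=d["cell_volume_ul"],
            temperature_c=d["temperature_c"],
            cell_concentration_um=d["cell_concentration_um"],
            syringe_concentration_mm=d["syringe_concentration_mm"],
            injections=injections,
            stir_note=d.get("stir_note", ""),
        )
    except KeyError as exc:
        raise ThermogramFormatError(f"sidecar missing field {exc}") from exc


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".setup.json")


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    """Write trace CSV plus the ``.setup.json`` sidecar, full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for key, value in tg.provenance.items():
            fh.write(f"# {key}={value}\n")
        fh.write("time_s,power_ucal_per_s\n")
        for t, p in zip(tg.time_s, tg.power_ucal_s):
            fh.write(f"{float(t)!r},{float(p)!r}\n")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(_setup_to_dict(tg.setup), fh, indent=1)


def read_thermogram(path: str | Path) -> Thermogram:
    """Read a trace CSV and its sidecar; round-trips ``write_thermogram``."""
    path = Path(path)
    if not path.exists():
        raise ThermogramFormatError(f"no such thermogram: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ThermogramFormatError(f"missing sidecar {sidecar}")
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _HEADER:
            raise ThermogramFormatError(
                f"not a thermogram file (header {first!r})")
        provenance: dict[str, str] = {}
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            provenance[key.strip()] = value
            line = fh.readline()
        columns = [c.strip() for c in line.rstrip("\n").split(",")]
        if columns != ["time_s", "power_ucal_per_s"]:
            raise ThermogramFormatError(f"unexpected columns {columns}")
        data = pd.read_csv(fh, names=columns, float_precision="round_trip")
    with open(sidecar) as fh:
        setup = _setup_from_dict(json.load(fh))
    return Thermogram(
        time_s=data["time_s"].to_numpy(),
        power_ucal_s=data["power_ucal_per_s"].to_numpy(),
        setup=setup,
        provenance=provenance,
    )


def estimate_baseline(
    tg: Thermogram, quiet_window_s: float = 30.0, min_samples: int = 5
) -> np.ndarray:
    """Piecewise-linear baseline anchored on pre-injection quiet windows.

    Each anchor is (window midpoint, median power over the window) for the
    quiet window ending at every injection start; a final anchor uses the
    trailing ``quiet_window_s`` of the trace.  The baseline is linear
    between anchors and extended flat beyond the first/last anchor.

    A window shorter than ``min_samples`` samples is widened toward the
    previous injection; if still too short, :class:`BaselineError`.
    """
    t, p = tg.time_s, tg.power_ucal_s
    dt = tg.dt_s
    anchors_t, anchors_p = [], []
    prev_end = t[0]
    for inj in tg.setup.injections:
        w0 = max(inj.start_s - quiet_window_s, prev_end)
        mask = (t >= w0) & (t < inj.start_s)
        if mask.sum() < min_samples:  # widen back to the previous injection end
            mask = (t >= prev_end) & (t < inj.start_s)
        if mask.sum() < min_samples:
            raise BaselineError(
                f"quiet window before t={inj.start_s:g}s has "
                f"{int(mask.sum())} < {min_samples} samples")
        anchors_t.append(0.5 * (t[mask][0] + t[mask][-1]))
        anchors_p.append(float(np.median(p[mask])))
        prev_end = inj.start_s + inj.duration_s
    tail = t >= t[-1] - quiet_window_s + dt
    tail &= t >= prev_end
    if tail.sum() >= min_samples:
        anchors_t.append(0.5 * (t[tail][0] + t[tail][-1]))
        anchors_p.append(float(np.median(p[tail])))
    if not anchors_t:
        raise BaselineError("no quiet windows found")
    return np.interp(t, anchors_t, anchors_p)


def integrate_peaks(
    tg: Thermogram,
    baseline: np.ndarray | None = None,
) -> HeatSeries:
    """Integrate each injection peak of a baseline-corrected trace.

    The window for injection i runs from its start to the next injection's
    start (or end of trace for the last one); trapezoidal quadrature on the
    uniform grid.  Integrals cut short by the end of trace are flagged.
    """
    if baseline is None:
        baseline = estimate_baseline(tg)
    t = tg.time_s
    corrected = tg.power_ucal_s - baseline
    injections = tg.setup.injections
    starts = [inj.start_s for inj in injections] + [np.inf]

    ledger = displacement_ledger(tg.setup)
    ratios = ledger.molar_ratio()

    spacings = np.diff([inj.start_s for inj in injections])
    nominal = float(np.median(spacings)) if spacings.size else t[-1] - starts[0]

    q_raw, truncated = [], []
    for i, inj in enumerate(injections):
        lo, hi = starts[i], min(starts[i + 1], t[-1])
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            q_raw.append(0.0)
            truncated.append(True)
            continue
        q_raw.append(float(np.trapezoid(corrected[mask], t[mask])))
        # partial if the trace ends before the window would nominally close
        truncated.append(bool(t[-1] < lo + min(nominal, starts[i + 1] - lo)))
    q_raw = np.asarray(q_raw)
    q_molar = np.array(
        [ucal_to_kj(q) / m for q, m in zip(q_raw, ledger.injected_moles)]
    )
    return HeatSeries(
        injection=np.arange(1, len(injections) + 1),
        q_ucal=q_raw,
        q_kj_per_mol=q_molar,
        molar_ratio=ratios,
        truncated=np.asarray(truncated, dtype=bool),
    )


def instrument_baseline(tg: Thermogram) -> np.ndarray:
    """Constant baseline from the pre-titration segment of the trace.

    A kinetics trace need not return to baseline between injections
    (substrate accumulates), so the between-injection quiet windows of
    :func:`estimate_baseline` are not usable; the only guaranteed quiet
    region is before the first injection.
    """
    mask = tg.time_s < tg.setup.injections[0].start_s
    if mask.sum() < 5:
        raise BaselineError("fewer than 5 samples before the first injection")
    return np.full_like(tg.power_ucal_s, float(np.median(tg.power_ucal_s[mask])))


def heat_flow_to_rate(
    tg: Thermogram,
    dh_app_kj_mol: float,
    tau_s: float = 0.0,
    baseline: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convert a hydrolysis thermogram to a reaction-rate series with [S](t).

    v(t) = P_corrected(t) / (dH_app · V0), where P_corrected applies the
    Tian correction P + τ·dP/dt when τ > 0.  The substrate concentration is
    reconstructed by crediting each injection through the displacement
    ledger and subtracting (and diluting) the cumulative hydrolysis implied
    by v(t) itself.  The default baseline is the pre-titration
    :func:`instrument_baseline` (kinetics traces do not return to baseline
    between injections).

    Returns a DataFrame with columns ``time_s``, ``v_um_s`` (µmol/L/s) and
    ``S_um`` (µmol/L).
    """
    if dh_app_kj_mol == 0:
        raise ItcError("dH_app = 0: rate undefined")
    if baseline is None:
        baseline = instrument_baseline(tg)
    p = tg.power_ucal_s - baseline
    if tau_s > 0:
        p = p + tau_s * np.gradient(p, tg.time_s)
    # µcal/s -> kJ/s is ucal_to_kj; v [mol/L/s] = P/(dH*V0); report µmol/L/s
    v = ucal_to_kj(p) / (dh_app_kj_mol * tg.setup.cell_volume_l) * 1e6

    t = tg.time_s
    dt = tg.dt_s
    v0_ul = tg.setup.cell_volume_ul
    c_syr = tg.setup.syringe_concentration_um
    s = np.empty_like(v)
    s_cur = 0.0
    inj_iter = iter(tg.setup.injections)
    nxt = next(inj_iter, None)
    for k in range(t.size):
        while nxt is not None and t[k] >= nxt.start_s:
            x = nxt.volume_ul / v0_ul
            f = (1 - x / 2) / (1 + x / 2)
            s_cur = s_cur * f + c_syr * x / (1 + x / 2)
            nxt = next(inj_iter, None)
        s_cur = max(s_cur - max(v[k], 0.0) * dt, 0.0)
        s[k] = s_cur
    return pd.DataFrame({"time_s": t, "v_um_s": v, "S_um": s})
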