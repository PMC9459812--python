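"""Shared definition of the simulated ITC campaign driven by the numbered
analysis scripts.

The campaign mirrors the published experimental design: 200 µL cell with
1 µmol/L acetylcholinesterase, 1 mmol/L titrant in the syringe (inhibitor
or acetylcholine), 36.6 °C.  Binding titrations use 19 x 2 µL injections
every 180 s; kinetics runs use 12 x 5 µL every 60 s so substrate
accumulates through Km.  Ground-truth parameters are the published
per-inhibitor values; because the raw thermograms are unavailable, every
downstream number here is a *recovery* of a known simulation truth, never a
reproduction of the published measurement.
"""

from __future__ import annotations

import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

import itcfit as m  # noqa: E402
from itcfit.datasets import KM_ACH_UM, thermodynamic_table  # noqa: E402

SCRATCH = REPO / "scratch" / "thermograms"
RESULTS = REPO / "results"

BINDING_SETUP = m.ExperimentSetup()
KINETICS_SETUP = m.ExperimentSetup(injections=tuple(
    m.default_schedule(n_injections=12, volume_ul=5.0, spacing_s=60.0,
                       first_start_s=60.0)))
INSTRUMENT = m.InstrumentModel(response_tau_s=10.0)
POWER_SIGMA = 0.0002         # µcal/s (~0.8 nW RMS), modern small-cell noise
VMAX_UM_S = 0.3              # enzyme loading chosen so peaks span Km
DH_APP_KJ_MOL = 20.0         # endothermic apparent hydrolysis enthalpy
DILUTION_HEAT_UCAL = -0.4    # per-injection titrant dilution heat
EI_HEAT_UCAL = -0.3          # residual enzyme-inhibitor heat, inhibited runs
INHIBITOR_UM_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)  # for the dose curve
KI_TRUTH_UM = 1.12


def noise(seed: int) -> m.NoiseModel:
    return m.NoiseModel(power_sigma_ucal_s=POWER_SIGMA, seed=seed)


def binding_truths() -> dict[str, m.BindingParams]:
    """Per-inhibitor single-site truths from the published table."""
    table = thermodynamic_table()
    return {
        name: m.BindingParams(n=1.0, kd_um=row["kd_um"],
                              dh_kj_mol=row["dh_kj_mol"])
        for name, row in table.iterrows()
    }


def slugify(name: str) -> str:
    return name.lower().replace(" ", "_").replace("/", "-")


def simulate_campaign(seed: int, outdir: Path = SCRATCH) -> dict[str, Path]:
    """Simulate every trace of the campaign; returns name -> CSV path."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, tg: m.Thermogram) -> None:
        path = outdir / f"{slugify(name)}.csv"
        m.write_thermogram(tg, path)
        paths[name] = path

    for k, (name, truth) in enumerate(binding_truths().items()):
        tg = m.simulate_binding_titration(
            truth, BINDING_SETUP, INSTRUMENT, noise(seed + k))
        save(f"binding {name}", tg)

    save("dilution control", m.simulate_dilution_control(
        BINDING_SETUP, DILUTION_HEAT_UCAL, INSTRUMENT, noise(seed + 50)))
    save("dilution substrate", m.simulate_dilution_control(
        KINETICS_SETUP, DILUTION_HEAT_UCAL, INSTRUMENT, noise(seed + 51)))

    save("hydrolysis uninhibited", m.simulate_hydrolysis(
        m.KineticTruth(km_um=KM_ACH_UM, vmax_um_s=VMAX_UM_S,
                       dh_app_kj_mol=DH_APP_KJ_MOL),
        KINETICS_SETUP, INSTRUMENT, noise(seed + 100)))

    for k, i_um in enumerate(INHIBITOR_UM_GRID):
        truth = m.KineticTruth(km_um=KM_ACH_UM, vmax_um_s=VMAX_UM_S,
                               ki_um=KI_TRUTH_UM, inhibitor_um=i_um,
                               dh_app_kj_mol=DH_APP_KJ_MOL)
        save(f"hydrolysis I={i_um}uM", m.simulate_hydrolysis(
            truth, KINETICS_SETUP, INSTRUMENT, noise(seed + 200 + k)))
    return paths


def load_or_simulate(seed: int) -> dict[str, m.Thermogram]:
    """Read campaign traces from scratch if present, else simulate."""
    paths = {p.stem: p for p in SCRATCH.glob("*.csv")}
    if not paths:
        simulate_campaign(seed)
        paths = {p.stem: p for p in SCRATCH.glob("*.csv")}
    return {name: m.read_thermogram(p) for name, p in sorted(paths.items())}
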