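"""Experiment description: cell, syringe, injection schedule, instrument
response and noise.

The default :class:`ExperimentSetup` mirrors a small-volume titration
calorimeter loaded for an enzyme-binding assay: a 200 µL cell holding
1 µmol/L macromolecule (acetylcholinesterase), a syringe at 1 mmol/L
ligand, 36.6 °C, and 19 injections of 2 µL spaced 180 s apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ScheduleError
from .units import celsius_to_kelvin


@dataclass(frozen=True)
class Injection:
    """One syringe injection: volume in µL, start time and duration in s."""

    volume_ul: float
    start_s: float
    duration_s: float = 4.0

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ScheduleError(f"injection volume must be > 0, got {self.volume_ul}")
        if self.duration_s <= 0:
            raise ScheduleError("injection duration must be > 0")


def default_schedule(
    n_injections: int = 19,
    volume_ul: float = 2.0,
    spacing_s: float = 180.0,
    first_start_s: float = 60.0,
    duration_s: float = 4.0,
) -> list[Injection]:
    """Evenly spaced equal-volume injections, the standard titration design."""
    return [
        Injection(volume_ul, first_start_s + i * spacing_s, duration_s)
        for i in range(n_injections)
    ]


@dataclass(frozen=True)
class ExperimentSetup:
    """Cell/syringe loading and injection schedule for one titration.

    Parameters
    ----------
    cell_volume_ul : active cell volume V0 (µL); the cell is always full and
        injections displace liquid out (perfusion geometry).
    temperature_c : bath temperature, °C.
    cell_concentration_um : macromolecule concentration in the cell, µmol/L.
    syringe_concentration_mm : titrant concentration in the syringe, mmol/L.
    injections : the schedule; starts must be strictly increasing and
        windows non-overlapping.
    """

    cell_volume_ul: float = 200.0
    temperature_c: float = 36.6
    cell_concentration_um: float = 1.0
    syringe_concentration_mm: float = 1.0
    injections: tuple[Injection, ...] = field(
        default_factory=lambda: tuple(default_schedule())
    )
    stir_note: str = "continuous stirring"

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0:
            raise ScheduleError("cell volume must be > 0")
        starts = [inj.start_s for inj in self.injections]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ScheduleError("injection start times must be strictly increasing")
        for a, b in zip(self.injections, self.injections[1:]):
            if a.start_s + a.duration_s > b.start_s:
                raise ScheduleError(
                    f"injection windows overlap at t={a.start_s:g}s"
                )
        for inj in self.injections:
            if inj.volume_ul >= self.cell_volume_ul:
                raise ScheduleError("injection volume must be smaller than the cell")

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    @property
    def cell_volume_l(self) -> float:
        return self.cell_volume_ul * 1e-6

    @property
    def syringe_concentration_um(self) -> float:
        return self.syringe_concentration_mm * 1e3

    def with_injections(self, injections: list[Injection]) -> "ExperimentSetup":
        return replace(self, injections=tuple(injections))


@dataclass(frozen=True)
class InstrumentModel:
    """First-order instrument response; tau = 0 means an ideal instrument."""

    response_tau_s: float = 10.0

    def __post_init__(self) -> None:
        if self.response_tau_s < 0:
            raise ValueError("response tau must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """White Gaussian power noise plus optional linear baseline drift.

    Identical seeds give bit-identical traces; seeds are explicit, never
    global state.
    """

    power_sigma_ucal_s: float = 0.0
    baseline_drift_ucal_s2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.power_sigma_ucal_s < 0:
            raise ValueError("power sigma must be >= 0")
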