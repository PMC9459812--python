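"""Physical constants and unit conversions.

The on-disk unit for differential power is µcal/s (the instrument's native
unit); thermodynamic outputs are reported in kJ/mol and J/(mol·K).  All
conversions funnel through the thermochemical calorie, 1 cal = 4.184 J.
"""

CAL_TO_J = 4.184
"""Thermochemical calorie in joules."""

R_GAS = 8.314
"""Gas constant, J/(mol·K)."""

KELVIN_OFFSET = 273.15

UCAL_PER_KJ = 1e9 / CAL_TO_J
"""µcal per kJ: 1 kJ = 1e9/4.184 µcal."""

LACTUCIN_MOLAR_MASS = 276.28
"""Molar mass of lactucin (C15H16O5), g/mol; used for lactucin-equivalent
molar doses of sesquiterpene-lactone extracts."""


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN_OFFSET


def ucal_to_kj(q_ucal: float) -> float:
    return q_ucal / UCAL_PER_KJ


def kj_to_ucal(q_kj: float) -> float:
    return q_kj * UCAL_PER_KJ
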