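"""Physical constants and unit conventions.

Units used throughout the package: millivolt (voltage), millimolar
(concentration/activity), inverse second (rate constants), picoampere
(current), degree Celsius (temperature in user-facing APIs).

Sign convention: positive membrane voltage means the internal (cis) side is
positive relative to the grounded external (trans) side, and positive current
is outward (K+ moving from the internal to the external solution).
"""

from __future__ import annotations

E_CHARGE = 1.602176634e-19
"""Elementary charge in coulomb (exact, SI 2019)."""

R_GAS = 8.31446261815324
"""Molar gas constant in J mol^-1 K^-1 (exact, SI 2019)."""

FARADAY = 96485.33212331001
"""Faraday constant in C mol^-1 (exact, N_A * e)."""

T_DEFAULT_C = 25.0
"""Default temperature in degree Celsius."""

ZERO_CELSIUS_K = 273.15

PA_PER_A = 1e12


def kelvin(t_celsius: float) -> float:
    """Convert Celsius to Kelvin."""
    return t_celsius + ZERO_CELSIUS_K


def thermal_voltage_mV(t_celsius: float = T_DEFAULT_C) -> float:
    """Thermal voltage RT/F in millivolt (~25.7 mV at 25 C, ~25.3 mV at 20 C)."""
    return 1e3 * R_GAS * kelvin(t_celsius) / FARADAY
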