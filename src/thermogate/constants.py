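"""Physical constants and unit helpers.

Model thermodynamics (sensor enthalpies/entropies) are kept in kcal·mol⁻¹,
the units in which thermo-TRP gating parameters are conventionally quoted;
Arrhenius activation energies are reported in kJ·mol⁻¹. Temperatures are
Kelvin internally and °C at every user-facing interface; voltages are mV.
"""

from __future__ import annotations

import numpy as np

#: Gas constant, kcal·mol⁻¹·K⁻¹ (model units for ΔH°, ΔS°).
R_KCAL = 1.987204258640832e-3

#: Gas constant, kJ·mol⁻¹·K⁻¹ (Arrhenius/Q10 units).
R_KJ = 8.31446261815324e-3

#: Gas constant, J·mol⁻¹·K⁻¹.
R_J = 8.31446261815324

#: Faraday constant, C·mol⁻¹.
F = 96485.33212331001

#: Exact thermochemical calorie conversion.
KCAL_TO_KJ = 4.184

ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(t_c):
    """Convert °C to K (scalar or array)."""
    return np.asarray(t_c, dtype=float) + ZERO_CELSIUS_K


def kelvin_to_celsius(t_k):
    """Convert K to °C (scalar or array)."""
    return np.asarray(t_k, dtype=float) - ZERO_CELSIUS_K


def thermal_voltage_mv(t_k):
    """RT/F in millivolts at absolute temperature ``t_k`` (≈25.693 mV at 298.15 K)."""
    return 1000.0 * R_J * np.asarray(t_k, dtype=float) / F
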