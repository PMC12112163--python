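"""Physical constants and unit helpers.

Internal unit system: mV, ms, mM, mS/cm^2, uA/cm^2, uF/cm^2; areas in um^2,
volumes in um^3 (converted to litres where moles are needed).
"""

import numpy as np

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
AVOGADRO = 6.02214076e23  # 1/mol

CELSIUS = 34.0  # model temperature tag
KELVIN = CELSIUS + 273.15

#: RT/F at 34 degC, in mV
RTF_MV = GAS_CONSTANT * KELVIN / FARADAY * 1e3

UM2_TO_CM2 = 1e-8
UM3_TO_L = 1e-15


def nernst(c_out: float, c_in: float, z: int = 1) -> float:
    """Nernst reversal potential (mV) at 34 degC."""
    return RTF_MV / z * np.log(c_out / c_in)


def current_to_flux(i_density, area_um2: float, volume_um3: float):
    """Convert a membrane current density (uA/cm^2, outward positive) to the
    rate of *loss* of the carried ion from the intracellular pool (mM/ms).
    """
    i_amp = i_density * (area_um2 * UM2_TO_CM2) * 1e-6
    return i_amp / (FARADAY * volume_um3 * UM3_TO_L)


def flux_to_current(flux_mm_per_ms, area_um2: float, volume_um3: float):
    """Inverse of :func:`current_to_flux` (mM/ms -> uA/cm^2, +1 charge)."""
    i_amp = flux_mm_per_ms * FARADAY * volume_um3 * UM3_TO_L
    return i_amp * 1e6 / (area_um2 * UM2_TO_CM2)


def mm_to_molecules(conc_mm, volume_um3: float):
    """Concentration (mM) in a compartment volume (um^3) -> molecule count."""
    return conc_mm * 1e-3 * volume_um3 * UM3_TO_L * AVOGADRO
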