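"""Physical constants and the unit conventions used across the package.

Internal unit system (NEURON-compatible):

==============  ==========
quantity        unit
==============  ==========
voltage         mV
time            ms
conductance     mS/cm^2 (density), mS (absolute), uS (axial)
current         uA/cm^2 (density, engine), mA/cm^2 (API), pA (stimuli)
capacitance     uF/cm^2 (specific), uF (absolute)
length          um
concentration   mM
resistivity     Ohm*cm
temperature     degC (config), K (Nernst)
==============  ==========

All unit conversions live here; no other module hard-codes a conversion
factor.
"""

import numpy as np

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.314462  # J/(mol*K)
CA_VALENCE = 2

#: reference temperature of every shipped kinetics set (degC).  Gating rates
#: are stored already normalized to this temperature; the simulator applies
#: no Q10 scaling at run time.
KINETICS_TEMP_C = 30.0

UM2_TO_CM2 = 1e-8
PA_TO_UA = 1e-6
MV_PA_TO_GOHM = 1.0  # R[GOhm] = dV[mV] / dI[pA]


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def sphere_area_um2(radius_um: float) -> float:
    """Surface area of a spherical compartment (um^2)."""
    return 4.0 * np.pi * radius_um**2


def cylinder_area_um2(diam_um: float, length_um: float) -> float:
    """Lateral surface area of a cylindrical compartment (um^2)."""
    return np.pi * diam_um * length_um
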