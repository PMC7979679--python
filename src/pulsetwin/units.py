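"""Unit conversions.

Disk/CLI formats use clinical units (cm, mmHg, mL/s, L/min); everything
in memory is SI (m, Pa, m^3/s).
"""

MMHG = 133.322387415  # Pa per mmHg
CM = 1e-2             # m per cm
ML = 1e-6             # m^3 per mL
L_MIN = 1e-3 / 60.0   # m^3/s per L/min


def mmhg_to_pa(p):
    return p * MMHG


def pa_to_mmhg(p):
    return p / MMHG


def cm_to_m(x):
    return x * CM


def m_to_cm(x):
    return x / CM


def area_from_diameter(d):
    """Lumen area (m^2) of a circular cross-section of diameter d (m)."""
    import numpy as np

    return np.pi * d * d / 4.0


def diameter_from_area(a):
    import numpy as np

    return np.sqrt(4.0 * a / np.pi)
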