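"""Unit conversions at the I/O boundary.

Internally everything is SI: conductivity in S/m, length in metres, current in
amperes, current density in A/m^2, potential in volts.  Electrode weights are
exposed in mA and current densities in mA/cm^2 because those are the units the
tDCS literature reports.
"""

MM_PER_M = 1000.0

#: 1 A/m^2 expressed in mA/cm^2  (1 A/m^2 = 1000 mA / 10^4 cm^2)
A_PER_M2_TO_MA_PER_CM2 = 0.1


def mA_to_A(x):
    return x * 1e-3


def A_to_mA(x):
    return x * 1e3


def mm_to_m(x):
    return x / MM_PER_M


def m_to_mm(x):
    return x * MM_PER_M


def A_m2_to_mA_cm2(x):
    return x * A_PER_M2_TO_MA_PER_CM2


def mA_cm2_to_A_m2(x):
    return x / A_PER_M2_TO_MA_PER_CM2
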