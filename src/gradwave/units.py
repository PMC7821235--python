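"""Unit conventions and conversion helpers.

Everything inside :mod:`gradwave` is SI: gradients in T/m, time in s,
dephasing in rad/m, b-tensors in s/m^2.  Reporting units used at the I/O
boundary follow MRI convention: gradient amplitude in mT/m, time in ms,
b-value in ms/um^2 and the Maxwell (concomitant-field) index in (mT/m)^2 ms.
"""

#: Gyromagnetic ratio of hydrogen (rad/s/T).
GAMMA_H = 2.675e8

#: 1 ms/um^2 expressed in s/m^2.
B_MS_UM2 = 1.0e9

#: 1 (T/m)^2 s expressed in (mT/m)^2 ms.
MAXWELL_REPORT = 1.0e9


def b_to_si(b_ms_um2: float) -> float:
    """Convert a b-value from ms/um^2 to s/m^2."""
    return b_ms_um2 * B_MS_UM2


def b_from_si(b_si: float) -> float:
    """Convert a b-value from s/m^2 to ms/um^2."""
    return b_si / B_MS_UM2


def maxwell_from_si(m_si: float) -> float:
    """Convert a Maxwell index from (T/m)^2 s to (mT/m)^2 ms."""
    return m_si * MAXWELL_REPORT
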