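"""Unit conversions.

The package works in CGS internally (dyn, cm, s; resistances in
dyn*s/cm^5, compliances in cm^5/dyn) and exposes clinical units at the
interface (pressures in mmHg, flows in mL/s; note 1 mL/s == 1 cm^3/s,
so flow needs no conversion).
"""

MMHG_TO_DYN_CM2 = 1333.22
"""Conversion constant: 1 mmHg in dyn/cm^2."""


def mmhg_to_cgs(p_mmhg):
    """Convert pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN_CM2


def cgs_to_mmhg(p_dyn_cm2):
    """Convert pressure from dyn/cm^2 to mmHg."""
    return p_dyn_cm2 / MMHG_TO_DYN_CM2
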