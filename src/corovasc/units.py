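"""Unit conventions and conversion constants.

All quantities cross module interfaces in the units clinicians and
morphometry tables use: lengths and radii in mm, pressures in mmHg, flows
in mm^3/s.  Resistances and the linear solve live in SI internally
(m, Pa, m^3/s); conversions happen exactly once at the boundary.
"""

MMHG_TO_PA = 133.322
M_PER_MM = 1e-3
M3_PER_MM3 = 1e-9
MM3_PER_M3 = 1e9


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA
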