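"""Unit conversions between SI and the reporting units of valve hydrodynamics.

Internally the package works in SI (m, s, Pa, kg).  Valve performance
metrics are reported in the units conventional for pulse-duplicator
testing: pressure gradients in mmHg, flow in mL/s, orifice areas in cm²,
stress accumulation in Pa·s.
"""

from __future__ import annotations

#: Pascals per millimetre of mercury.
PA_PER_MMHG = 133.322387415

#: Pascals per dyne/cm².
PA_PER_DYNE_CM2 = 0.1


def mmhg_to_pa(dp_mmhg: float) -> float:
    return dp_mmhg * PA_PER_MMHG


def pa_to_mmhg(dp_pa: float) -> float:
    return dp_pa / PA_PER_MMHG


def dyne_s_cm2_to_pa_s(sa: float) -> float:
    """Convert stress accumulation from dyne·s/cm² to Pa·s.

    The Hellums platelet-activation threshold is quoted as
    35 dyne·s/cm², i.e. 3.5 Pa·s.
    """
    return sa * PA_PER_DYNE_CM2


def kg_m3_to_g_cm3(rho: float) -> float:
    return rho / 1000.0


#: Hellums platelet-activation threshold in dyne·s/cm².
HELLUMS_THRESHOLD_DYNE_S_CM2 = 35.0

#: The same threshold in Pa·s, derived — not hard-coded — from the CGS value.
HELLUMS_THRESHOLD_PA_S = dyne_s_cm2_to_pa_s(HELLUMS_THRESHOLD_DYNE_S_CM2)
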