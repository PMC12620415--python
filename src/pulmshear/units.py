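"""Unit conversion constants.

All internal computation is CGS (dyn, cm, s). Clinical units (mmHg, Wood
units, L/min) are converted at module boundaries.
"""

MMHG = 1333.22
"""dyn/cm^2 per mmHg."""

WOOD = 80.0
"""dyn*s/cm^5 per Wood unit."""

LPM = 1000.0 / 60.0
"""cm^3/s per L/min."""

POISE_PER_PAS = 10.0
"""poise (g/(cm*s)) per Pa*s."""


def mmhg_to_cgs(p: float) -> float:
    return p * MMHG


def cgs_to_mmhg(p: float) -> float:
    return p / MMHG


def lpm_to_cgs(q: float) -> float:
    return q * LPM


def wood_to_cgs(r: float) -> float:
    return r * WOOD
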