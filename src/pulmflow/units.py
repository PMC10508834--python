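"""Unit conversions.

All internal computation is in CGS (cm, g, s); pressures are g/(cm s^2)
(barye = 0.1 Pa). mmHg appears only at I/O boundaries.
"""

MMHG_TO_CGS = 1333.22  # 1 mmHg in g/(cm s^2)


def mmhg_to_cgs(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_CGS


def cgs_to_mmhg(p_cgs: float) -> float:
    return p_cgs / MMHG_TO_CGS
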