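"""Unit conventions and conversions.

All internal computation is in CGS (cm, g, s, dyn/cm^2). Pressures cross the
user interface in mmHg, flows in mL/s (identical to cm^3/s) or mL/min where
noted.
"""

MMHG_TO_DYN: float = 1333.22
"""1 mmHg in dyn/cm^2."""


def mmhg_to_dyn(p_mmhg):
    """Convert pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN


def dyn_to_mmhg(p_dyn):
    """Convert pressure from dyn/cm^2 to mmHg."""
    return p_dyn / MMHG_TO_DYN


def mlmin_to_mls(q):
    """Convert flow from mL/min to mL/s."""
    return q / 60.0
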