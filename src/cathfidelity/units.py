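"""Unit conventions and conversions.

The package works in SI units internally (Pa, m, s, kg); pressures cross the
API boundary in mmHg, the clinical currency of catheter-lab measurements.
"""

MMHG_TO_PA: float = 133.322
"""1 mmHg in pascal."""


def mmhg_to_pa(p_mmhg):
    """Convert a pressure (scalar or array) from mmHg to Pa."""
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa):
    """Convert a pressure (scalar or array) from Pa to mmHg."""
    return p_pa / MMHG_TO_PA
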