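"""Published parameter presets for input-filter types and simulated units.

Thirteen Gabor STRF variants differ only in normalization factor ``a``
and temporal phase ``P_t``; each simulated neural unit pairs one STRF
variant with a spike-rate-adaptation conductance for its cortical
neuron.  Four STRF variants have no printed temporal phase; they default
to pi/2.  Unit 23 is listed under two STRF variants in the source table;
the first listing (STRF 1) is kept.
"""

from __future__ import annotations

import math

__all__ = ["STRF_TABLE", "UNIT_TABLE", "strf_preset_values", "unit_preset"]

_DEFAULT_PT = math.pi / 2

# strf_no -> (normalization factor a, temporal phase P_t in radians)
STRF_TABLE: dict[int, tuple[float, float]] = {
    1: (0.08, 1.4608),
    2: (0.1, 1.4923),
    3: (0.07, 1.508),
    4: (0.1, _DEFAULT_PT),
    5: (0.12, 1.5237),
    6: (0.1, 1.5394),
    7: (0.07, 1.5425),
    8: (0.087, _DEFAULT_PT),
    9: (0.15, 1.5582),
    10: (0.05, _DEFAULT_PT),
    11: (0.08, _DEFAULT_PT),
    12: (0.16, 1.5598),
    13: (0.17, 1.5708),
}

# unit number -> (strf_no, adaptation conductance, leak units)
UNIT_TABLE: dict[int, tuple[int, float]] = {
    3: (1, 0.025), 6: (1, 0.025), 9: (1, 0.025), 10: (1, 0.025),
    11: (1, 0.025), 13: (1, 0.025), 21: (1, 0.025), 23: (1, 0.025),
    14: (1, 0.04), 22: (1, 0.04),
    15: (2, 0.0),
    29: (3, 0.12), 27: (3, 0.1),
    7: (4, 0.07),
    19: (5, 0.06),
    2: (6, 0.06),
    5: (7, 0.2), 25: (7, 0.16),
    20: (8, 0.07), 32: (8, 0.07),
    1: (8, 0.08), 12: (8, 0.08), 33: (8, 0.08),
    16: (9, 0.09),
    8: (10, 0.09),
    4: (11, 0.09),
    26: (12, 0.03), 28: (12, 0.03), 31: (12, 0.03),
    17: (13, 0.01), 18: (13, 0.03),
}


def strf_preset_values(strf_no: int) -> tuple[float, float]:
    """(a, P_t) for a given STRF variant number (1-13)."""
    try:
        return STRF_TABLE[int(strf_no)]
    except KeyError:
        raise KeyError(f"unknown STRF no. {strf_no}; valid keys are 1-13") from None


def unit_preset(unit: int) -> tuple[int, float]:
    """(strf_no, adaptation conductance) for a simulated neural unit."""
    try:
        return UNIT_TABLE[int(unit)]
    except KeyError:
        raise KeyError(f"unknown neural unit {unit}") from None
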