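"""Stable-isotope delta notation.

δ13C is reported against the Vienna Pee Dee Belemnite carbonate standard
and δ15N against atmospheric air:

    δ = (R_sample / R_standard − 1) × 1000   [per mil]

with R the heavy/light isotope ratio (13C/12C or 15N/14N).  The standard
ratios are parameters rather than hardcoded constants, so any calibration
convention can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Element(str, Enum):
    C = "C"   # reference standard: VPDB
    N = "N"   # reference standard: atmospheric air


@dataclass(frozen=True)
class IsotopeMeasurement:
    ratio_sample: float
    ratio_standard: float
    element: Element = Element.C

    def __post_init__(self) -> None:
        if self.ratio_sample <= 0 or self.ratio_standard <= 0:
            raise ValueError("isotope ratios must be positive")


def delta_value(m: IsotopeMeasurement) -> float:
    """Per-mil deviation of the sample ratio from the standard."""
    return (m.ratio_sample / m.ratio_standard - 1.0) * 1000.0
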