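"""Transmit (B1) reference-voltage calibration from a STEAM double-voltage
water acquisition.

A STEAM water spectrum is acquired twice, at reference voltages of 100 V
and 200 V.  The stimulated-echo amplitude scales as sin^3(theta) with the
flip angle theta, and doubling the voltage doubles the flip, so the ratio

    S2 / S1 = sin^3(2 theta) / sin^3(theta) = 8 cos^3(theta)

yields theta directly; the voltage producing a true 90 degree flip follows
by proportionality:

    V_ref = 90 * 100 / ((180 / pi) * acos( cbrt(S2 / (8 S1)) ))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["B1CalInput", "reference_voltage"]


@dataclass(frozen=True)
class B1CalInput:
    """Water peak amplitudes at 100 V (``s1``) and 200 V (``s2``).

    A slightly negative ``s2`` (a noise-limited amplitude estimate) is
    clamped to zero with a warning rather than rejected.
    """

    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.s1 <= 0:
            raise ValueError("s1 must be positive")
        if self.s2 < 0:
            warnings.warn("negative s2 clamped to 0 (noise floor)", stacklevel=2)
            object.__setattr__(self, "s2", 0.0)
        if self.s2 >= 8.0 * self.s1:
            raise ValueError("need s2 < 8*s1 (acos domain)")


def reference_voltage(inp: B1CalInput) -> float:
    """Optimal reference voltage in volts (flip angle 90 degrees).

    Equals ``9000 / theta_deg`` where ``theta_deg`` is the flip angle
    actually produced at 100 V.
    """
    theta_deg = math.degrees(math.acos((inp.s2 / (8.0 * inp.s1)) ** (1.0 / 3.0)))
    return 90.0 * 100.0 / theta_deg
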