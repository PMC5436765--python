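"""Asymmetric 24 h circadian forcing of CRH production.

D(t) = d1 - 0.079145093*d2
       + (0.064*sin(2*pi*(t-840)/1440) + 0.12*|sin(pi*(t-840)/1440)|) * d2

with t in minutes since 00:00 of day 1.  The phase 840 min puts the zero of
both trigonometric terms at 14:00, so the maximum of the drive falls in the
late light phase, consistent with the nocturnal corticosterone rise in rats.
The rectified-sine term makes the waveform asymmetric about its maximum.
With default parameters D is strictly positive (minimum ~0.066 near 12:27)
and 1440-min periodic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ForcingParams", "DEFAULT_FORCING", "circadian_drive"]


@dataclass(frozen=True)
class ForcingParams:
    d1: float = 0.2662
    d2: float = 2.5
    offset_coefficient: float = 0.079145093
    sine_amplitude: float = 0.064
    rectified_amplitude: float = 0.12
    phase_minutes: float = 840.0
    period_minutes: float = 1440.0

    def __post_init__(self) -> None:
        if self.period_minutes <= 0:
            raise ValueError("period must be positive")


DEFAULT_FORCING = ForcingParams()


def circadian_drive(t, params: ForcingParams = DEFAULT_FORCING):
    """Evaluate D(t) (dimensionless). Accepts scalars or arrays, any real t."""
    t = np.asarray(t, dtype=float)
    p = params
    x = (t - p.phase_minutes) / p.period_minutes
    wave = p.sine_amplitude * np.sin(2.0 * np.pi * x) + p.rectified_amplitude * np.abs(
        np.sin(np.pi * x)
    )
    out = p.d1 - p.offset_coefficient * p.d2 + wave * p.d2
    return float(out) if out.ndim == 0 else out
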