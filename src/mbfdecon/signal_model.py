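"""Saturation-recovery signal <-> concentration conversion for the AIF.

A saturation-recovery prepared acquisition yields a signal
``S_N(R1) = S0 * (1 - exp(-TD * R1))`` where S0 is the proton-density
signal and TD the saturation delay.  Inverting this gives the longitudinal
relaxation rate R1, and the contrast-agent concentration follows from the
linear relaxivity relation ``R1 = R1_baseline + r1 * C``.

The digital phantom works directly in concentration space and never touches
this module; it applies only to user-supplied signal curves.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SaturationSignalParams",
    "r1_from_saturation_signal",
    "concentration_from_r1",
    "saturation_signal_from_r1",
    "SaturationClippingError",
]


class SaturationClippingError(ValueError):
    """Signal at or above S0 is inconsistent with the saturation model."""


@dataclasses.dataclass(frozen=True)
class SaturationSignalParams:
    """Saturation-recovery acquisition constants.

    S0 : proton-density signal (arbitrary units).
    TD : saturation delay, s.
    R1_baseline : pre-contrast relaxation rate, 1/s.
    relaxivity_r1 : contrast-agent r1 relaxivity, L/(mmol*s).  Default 3.5
        (gadoterate at 3 T).
    """

    S0: float
    TD: float
    R1_baseline: float = 1.0
    relaxivity_r1: float = 3.5

    def __post_init__(self) -> None:
        if self.S0 <= 0 or self.TD <= 0 or self.relaxivity_r1 <= 0:
            raise ValueError("S0, TD and relaxivity must be > 0")


def saturation_signal_from_r1(R1, p: SaturationSignalParams):
    """Forward model S_N = S0 * (1 - exp(-TD * R1))."""
    return p.S0 * (-np.expm1(-p.TD * np.asarray(R1, dtype=float)))


def r1_from_saturation_signal(SN, p: SaturationSignalParams):
    """Invert the saturation-recovery signal equation for R1 (1/s).

    Valid for 0 <= SN < S0.  Signals at or above S0 raise
    :class:`SaturationClippingError`; negative signals raise ValueError.
    """
    s = np.asarray(SN, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative signal is invalid")
    if np.any(s >= p.S0):
        raise SaturationClippingError(
            "signal >= S0 is inconsistent with the saturation-recovery model")
    r1 = -np.log1p(-s / p.S0) / p.TD
    return r1 if r1.ndim else float(r1)


def concentration_from_r1(R1, p: SaturationSignalParams,
                          return_flags: bool = False):
    """Concentration (mmol/L) from R1 via the linear relaxivity relation.

    C = (R1 - R1_baseline) / relaxivity, floored at 0.  With
    ``return_flags=True`` also returns a boolean mask of samples that fell
    below baseline (flagged, not an error).
    """
    r1 = np.asarray(R1, dtype=float)
    if np.any(r1 < 0):
        raise ValueError("R1 must be >= 0")
    diff = r1 - p.R1_baseline
    flagged = diff < 0
    conc = np.maximum(diff, 0.0) / p.relaxivity_r1
    if not conc.ndim:
        conc, flagged = float(conc), bool(flagged)
    return (conc, flagged) if return_flags else conc
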