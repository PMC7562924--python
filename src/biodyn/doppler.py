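"""Doppler frequency <-> intracellular speed conversion.

Backscattered light picks up a Doppler angular-frequency shift
``delta_omega = q * v`` from a scatterer moving at speed ``v``, where
``q = 4 pi n / lambda0`` is the backscattering momentum-transfer magnitude,
``n`` the tissue refractive index and ``lambda0`` the free-space wavelength.
In ordinary frequency units ``f = q v / (2 pi) = 2 n v / lambda0``: at
840 nm in tissue (n = 1.33) a speed of 1 micron/s maps to ~3 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DopplerConvention", "doppler_shift", "doppler_speed"]


@dataclass(frozen=True)
class DopplerConvention:
    """Optical constants for the Doppler relation.

    wavelength_nm: free-space source wavelength (default 840 nm, NIR SLD).
    refractive_index: tissue refractive index (default 1.33).
    """

    wavelength_nm: float = 840.0
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def q(self) -> float:
        """Backscattering momentum transfer 4*pi*n/lambda0 in rad/m."""
        return 4.0 * math.pi * self.refractive_index / (self.wavelength_nm * 1e-9)


def doppler_shift(speed_m_s: float, conv: DopplerConvention = DopplerConvention()) -> float:
    """Doppler frequency (Hz) of a scatterer moving at ``speed_m_s`` (m/s)."""
    if speed_m_s < 0:
        raise ValueError("speed must be non-negative")
    return conv.q * speed_m_s / (2.0 * math.pi)


def doppler_speed(frequency_hz: float, conv: DopplerConvention = DopplerConvention()) -> float:
    """Exact inverse of :func:`doppler_shift`: speed (m/s) for a shift in Hz."""
    if frequency_hz < 0:
        raise ValueError("frequency must be non-negative")
    return 2.0 * math.pi * frequency_hz / conv.q
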